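"""Standard-format I/O: NIfTI, DICOM series, centerline JSON/VTK, configs.

All geometry written by this package is in world millimetres with the
axis-aligned ``index * spacing`` convention; NIfTI affines are diagonal
spacing matrices, and volumes read from disk are reoriented to the
closest canonical axis order before use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pydicom
import yaml
from PIL import Image

from .phantoms import Branch, PhantomSample, PhantomSpec
from .types import Centerline, VesselMask, Volume3D

__all__ = [
    "ReadError", "read_volume", "write_volume", "read_mask", "write_mask",
    "read_centerlines_json", "write_centerlines_json", "write_centerlines_vtk",
    "write_cpr_png", "phantom_spec_to_yaml", "phantom_spec_from_yaml",
    "write_phantom_sample", "write_provenance",
]


class ReadError(IOError):
    """A file or series could not be read as a volume."""


def _read_nifti(path: Path, kind: str) -> Volume3D:
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ReadError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data, spacing, kind)


def _read_dicom_series(directory: Path, kind: str) -> Volume3D:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append((p, ds))
    if not slices:
        raise ReadError(f"{directory}: no readable DICOM slices")
    first = slices[0][1]
    orient = np.array(getattr(first, "ImageOrientationPatient",
                              [1, 0, 0, 0, 1, 0]), dtype=float)
    normal = np.cross(orient[:3], orient[3:])

    def zpos(ds):
        pos = np.array(getattr(ds, "ImagePositionPatient", [0, 0, 0]),
                       dtype=float)
        return float(pos @ normal)

    slices.sort(key=lambda t: zpos(t[1]))
    zs = np.array([zpos(ds) for _, ds in slices])
    if len(zs) > 1:
        steps = np.diff(zs)
        bad = np.flatnonzero(np.abs(steps - np.median(steps)) > 1e-3)
        if bad.size:
            names = [slices[i + 1][0].name for i in bad]
            raise ReadError(
                f"{directory}: inconsistent slice spacing at {names} "
                f"(steps {steps[bad]}, median {np.median(steps):.4f})")
        dz = float(np.median(steps))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    px = [float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0])]
    # stack slices along the last axis: (rows, cols, n_slices)
    data = np.stack([ds.pixel_array for _, ds in slices], axis=-1)
    return Volume3D(data.astype(np.float32), (px[0], px[1], abs(dz)), kind)


def read_volume(path, kind: str = "T1WI") -> Volume3D:
    """Read a NIfTI file or a DICOM series directory as a Volume3D."""
    p = Path(path)
    if not p.exists():
        raise ReadError(f"no such file or directory: {p}")
    if p.is_dir():
        return _read_dicom_series(p, kind)
    return _read_nifti(p, kind)


def write_volume(vol: Volume3D, path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine),
             str(path))


def write_mask(mask: VesselMask, path) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def read_mask(path) -> VesselMask:
    p = Path(path)
    if not p.exists():
        raise ReadError(f"no such file: {p}")
    img = nib.as_closest_canonical(nib.load(str(p)))
    data = np.rint(np.asanyarray(img.dataobj)).astype(np.uint8)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VesselMask(data, spacing)


# ---------------------------------------------------------------------------
# Centerlines
# ---------------------------------------------------------------------------

def write_centerlines_json(lines: list[Centerline], path) -> None:
    payload = [{
        "label": ln.label,
        "side": ln.side,
        "points_mm": np.round(ln.points, 6).tolist(),
        "bridged": [list(b) for b in ln.bridged],
        "complete": bool(ln.complete),
    } for ln in lines]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_centerlines_json(path) -> list[Centerline]:
    p = Path(path)
    if not p.exists():
        raise ReadError(f"no such file: {p}")
    with open(p) as fh:
        payload = json.load(fh)
    return [Centerline(np.asarray(item["points_mm"], dtype=float),
                       item["label"], item.get("side", "midline"),
                       bridged=[tuple(b) for b in item.get("bridged", [])],
                       complete=item.get("complete", True))
            for item in payload]


def write_centerlines_vtk(lines: list[Centerline], path) -> None:
    """Legacy-ASCII VTK polydata with one polyline per centerline."""
    total = sum(ln.n_points for ln in lines)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n"
                 "vessel centerlines (mm)\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {total} float\n")
        for ln in lines:
            for p in ln.points:
                fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        fh.write(f"LINES {len(lines)} {len(lines) + total}\n")
        offset = 0
        for ln in lines:
            idx = " ".join(str(offset + i) for i in range(ln.n_points))
            fh.write(f"{ln.n_points} {idx}\n")
            offset += ln.n_points


def write_cpr_png(pixels: np.ndarray, path, window: tuple[float, float] | None = None
                  ) -> None:
    """Windowed 8-bit preview of a CPR image (rows = arc length)."""
    if window is None:
        lo, hi = np.percentile(pixels, [1, 99])
    else:
        lo, hi = window
    if hi <= lo:
        hi = lo + 1.0
    img = np.clip((pixels - lo) / (hi - lo), 0, 1)
    Image.fromarray((img * 255).astype(np.uint8)).save(str(path))


# ---------------------------------------------------------------------------
# Phantom spec / config serialisation
# ---------------------------------------------------------------------------

def phantom_spec_to_yaml(spec: PhantomSpec, path) -> None:
    doc = {
        "grid_shape": list(spec.grid_shape),
        "spacing_mm": list(spec.spacing_mm),
        "noise_sigma": dict(spec.noise_sigma),
        "background_level": dict(spec.background_level),
        "lumen_level": dict(spec.lumen_level),
        "occluded_level": dict(spec.occluded_level),
        "seed": int(spec.seed),
        "branches": [{
            "label": b.label,
            "side": b.side,
            "control_points": np.asarray(b.control_points).tolist(),
            "radius_mm": np.asarray(b.radius_mm).tolist(),
            "occlusion_span": list(b.occlusion_span) if b.occlusion_span else None,
        } for b in spec.branches],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def phantom_spec_from_yaml(path) -> PhantomSpec:
    p = Path(path)
    if not p.exists():
        raise ReadError(f"no such file: {p}")
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    branches = [Branch(b["label"], np.asarray(b["control_points"], dtype=float),
                       np.asarray(b["radius_mm"], dtype=float),
                       side=b.get("side", "midline"),
                       occlusion_span=tuple(b["occlusion_span"])
                       if b.get("occlusion_span") else None)
                for b in doc.pop("branches")]
    doc["grid_shape"] = tuple(doc["grid_shape"])
    doc["spacing_mm"] = tuple(doc["spacing_mm"])
    return PhantomSpec(branches=branches, **doc)


def write_phantom_sample(sample: PhantomSample, out_dir, stem: str = "phantom"
                         ) -> dict[str, str]:
    """Write volumes (one NIfTI per sequence), the mask, and centerlines."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for kind, vol in sample.volumes.items():
        safe = kind.replace("-", "").lower()
        path = out / f"{stem}_{safe}.nii.gz"
        write_volume(vol, path)
        written[kind] = str(path)
    mask_path = out / f"{stem}_mask.nii.gz"
    write_mask(sample.mask, mask_path)
    written["mask"] = str(mask_path)
    lines_path = out / f"{stem}_centerlines.json"
    write_centerlines_json(sample.centerlines, lines_path)
    written["centerlines"] = str(lines_path)
    return written


def write_provenance(path, config_obj, seed: int) -> None:
    """Sidecar recording the configuration hash, seed and version."""
    from . import __version__
    if dataclasses.is_dataclass(config_obj) and not isinstance(config_obj, type):
        doc = dataclasses.asdict(config_obj)
    else:
        doc = dict(config_obj)
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    with open(path, "w") as fh:
        json.dump({
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": int(seed),
            "version": __version__,
            "config": doc,
        }, fh, indent=1, default=str)
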