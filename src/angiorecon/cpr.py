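"""Curved planar reformation (CPR) and the centerline-deviation rubric.

A straightened CPR resamples a 3D volume on planes orthogonal to a
vessel centerline: each output row is the in-plane intensity profile at
one arc-length station, so the whole curved vessel is rendered in a
single flat image. The in-plane sampling direction is carried along the
line by a rotation-minimizing frame and can be rotated by a viewing
angle to inspect the vessel from different sides.

The deviation rubric mechanises the quantitative part of a 4-point
reading score: a reconstruction whose centerline never leaves the
target lumen scores 1, up to 25% of its arc length outside scores 2,
up to 50% scores 3, and anything worse — or an unrecognised vessel —
scores 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .frames import rotation_minimizing_frames
from .types import Centerline, VesselMask, Volume3D

__all__ = ["CPRImage", "straightened_cpr", "deviation_fraction", "rubric_score"]


@dataclass
class CPRImage:
    """A 2D reformatted image: rows follow arc length, columns the plane."""

    pixels: np.ndarray
    along_spacing_mm: float
    cross_spacing_mm: float
    label: str
    kind: str
    rotation_angle_deg: float
    out_of_volume: np.ndarray    # bool grid: padded samples

    def __post_init__(self) -> None:
        if self.along_spacing_mm <= 0 or self.cross_spacing_mm <= 0:
            raise ValueError("CPR spacings must be positive")


def straightened_cpr(vol: Volume3D, line: Centerline, *,
                     half_width_mm: float = 10.0, step_mm: float = 0.5,
                     angle_deg: float = 0.0,
                     cross_spacing_mm: float | None = None,
                     padding_value: float | None = None,
                     interpolation_order: int = 1) -> CPRImage:
    """Straightened CPR of ``vol`` along ``line``.

    The centerline is resampled at a uniform ``step_mm``; a
    rotation-minimizing frame is transported along it, and each output
    row holds trilinear samples along the in-plane direction at
    ``angle_deg`` within ±``half_width_mm``. Samples falling outside
    the volume take ``padding_value`` (default: volume minimum) and are
    flagged in ``out_of_volume``.
    """
    if line.n_points < 2 or line.length == 0:
        raise ValueError("centerline too short for CPR")
    if step_mm <= 0 or half_width_mm <= 0:
        raise ValueError("step_mm and half_width_mm must be positive")
    cross = float(cross_spacing_mm if cross_spacing_mm is not None
                  else min(vol.spacing))
    pad = float(padding_value if padding_value is not None else vol.data.min())

    resampled = line.resample(step_mm)
    pts = resampled.points
    _, normals, binormals = rotation_minimizing_frames(pts)
    theta = np.deg2rad(angle_deg)
    inplane = np.cos(theta) * normals + np.sin(theta) * binormals

    n_cols_half = int(np.ceil(half_width_mm / cross))
    offsets = np.arange(-n_cols_half, n_cols_half + 1) * cross
    # sample positions: (rows, cols, 3) world mm
    sample = pts[:, None, :] + offsets[None, :, None] * inplane[:, None, :]
    coords = sample / np.asarray(vol.spacing)
    out = np.zeros(coords.shape[:2], dtype=bool)
    shape = np.asarray(vol.shape)
    out |= np.any(coords < 0, axis=2) | np.any(coords > shape - 1, axis=2)
    pixels = map_coordinates(vol.data.astype(float), coords.reshape(-1, 3).T,
                             order=interpolation_order, mode="constant",
                             cval=pad).reshape(coords.shape[:2])
    pixels[out] = pad
    return CPRImage(pixels, float(resampled.arc_length[1] - resampled.arc_length[0])
                    if resampled.n_points > 1 else step_mm,
                    cross, line.label, vol.kind, float(angle_deg), out)


def deviation_fraction(line: Centerline, target_lumen: VesselMask,
                       sample_mm: float | None = None) -> float:
    """Fraction of the centerline's arc length outside the target lumen.

    The line is sampled uniformly in arc length; a sample is outside
    when its nearest voxel does not carry the line's label. An empty
    target label returns 1.0 with a warning.
    """
    binary = target_lumen.binary(line.label)
    if not binary.any():
        warnings.warn(f"target label {line.label} empty in lumen mask; "
                      "deviation fraction = 1.0")
        return 1.0
    sp = np.asarray(target_lumen.spacing)
    step = float(sample_mm if sample_mm is not None else 0.25 * sp.min())
    if line.n_points < 2 or line.length == 0:
        pts = line.points
    else:
        res = line.resample(step)
        # midpoints carry the arc-length weight of their sub-segment
        pts = 0.5 * (res.points[:-1] + res.points[1:])
    vox = np.rint(pts / sp).astype(int)
    shape = np.asarray(binary.shape)
    ok = np.all((vox >= 0) & (vox < shape), axis=1)
    inside = np.zeros(len(pts), dtype=bool)
    if ok.any():
        v = vox[ok]
        inside[ok] = binary[v[:, 0], v[:, 1], v[:, 2]]
    return float(1.0 - inside.mean())


def rubric_score(dev: float, recognized_correctly: bool = True) -> int:
    """Quantitative 4-point reconstruction score (deviation rubric only).

    1 = recognised, centerline fully inside the target vessel;
    2 = recognised, deviation no more than 25% of arc length;
    3 = recognised, deviation no more than 50%;
    4 = deviation beyond 50%, or segmentation/recognition failure.

    This mechanises only the deviation thresholds of the reading scale;
    the human artefact/clarity judgements are out of scope.
    """
    if not 0.0 <= dev <= 1.0:
        raise ValueError(f"deviation fraction must be in [0, 1], got {dev}")
    if not recognized_correctly:
        return 4
    if dev == 0.0:
        return 1
    if dev <= 0.25:
        return 2
    if dev <= 0.5:
        return 3
    return 4
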