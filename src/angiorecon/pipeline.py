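"""End-to-end reconstruction pipeline: volumes in, CPR + centerlines out.

Phase I segments (and recognises) the arteries from whatever sequences
are available — dual-channel black-blood, single-channel bright-blood,
or both fused. Phase II extracts, connects and refines the labelled
centerlines and renders a straightened CPR per artery. A ground-truth
mask can stand in for the network ("oracle" segmenter), which keeps the
geometry phase testable in isolation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as aio
from .centerline import (DistanceField, connect_and_extend, default_adjacency,
                         load_adjacency, principal_centerlines,
                         refine_with_lumen, skeletonize)
from .cpr import deviation_fraction, rubric_score, straightened_cpr
from .metrics import centerline_accuracy, evaluate_masks, mcd
from .segmentation import (SegOutput, fuse_segmentations, load_model,
                           prepare_channels, segment)
from .types import LABEL_VALUES, BLACK_BLOOD, Centerline, VesselMask, Volume3D

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "load_pipeline_config", "ConfigError", "ComputeError"]

log = logging.getLogger("angiorecon")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class ComputeError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """Everything one reconstruction run needs."""

    inputs: dict[str, str] = dc_field(default_factory=dict)   # kind -> path
    black_checkpoint: Optional[str] = None
    bright_checkpoint: Optional[str] = None
    oracle_mask: Optional[str] = None      # ground-truth mask instead of models
    arteries: Optional[list[str]] = None   # None = all labels present
    truth_mask: Optional[str] = None
    truth_centerlines: Optional[str] = None
    adjacency: Optional[str] = None
    prune_len_mm: float = 3.0
    max_bridge_mm: float = 10.0
    tol_mm: float = 1.0
    cpr_half_width_mm: float = 10.0
    cpr_step_mm: float = 0.5
    cpr_angle_deg: float = 0.0
    cpr_sequence: Optional[str] = None     # default: first black-blood, else TOF
    output_dir: str = "angiorecon_out"
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    mask: VesselMask
    centerlines: list[Centerline]
    outputs: dict[str, str]
    metrics: Optional[dict] = None


def load_pipeline_config(path) -> PipelineConfig:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"no such config file: {p}")
    with open(p) as fh:
        doc = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig(**doc)
    except TypeError as exc:
        raise ConfigError(f"bad pipeline config: {exc}") from None


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except (ConfigError, aio.ReadError):
                raise
            except Exception as exc:
                raise ComputeError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("segmentation")
def _segment_phase(config: PipelineConfig, volumes: dict[str, Volume3D]
                   ) -> VesselMask:
    if config.oracle_mask is not None:
        log.info("using oracle segmentation mask %s", config.oracle_mask)
        return aio.read_mask(config.oracle_mask)
    prepared = prepare_channels(volumes)
    outputs: list[SegOutput] = []
    if prepared.black is not None and config.black_checkpoint:
        model = load_model(config.black_checkpoint)
        outputs.append(segment(model, prepared.black))
    if prepared.bright is not None and config.bright_checkpoint:
        model = load_model(config.bright_checkpoint)
        outputs.append(segment(model, prepared.bright))
    if not outputs:
        raise ConfigError("no applicable model checkpoint for the available "
                          "sequences (and no oracle mask)")
    if len(outputs) == 2:
        return fuse_segmentations(outputs[0], outputs[1])
    out = outputs[0]
    return VesselMask(out.mask.astype(np.uint8), out.spacing)


@_stage("centerline")
def _centerline_phase(config: PipelineConfig, mask: VesselMask
                      ) -> list[Centerline]:
    adjacency = (load_adjacency(config.adjacency) if config.adjacency
                 else default_adjacency())
    labels = config.arteries or mask.labels_present()
    lines: list[Centerline] = []
    for label in labels:
        skel = skeletonize(mask, label)
        lines.extend(principal_centerlines(skel, mask,
                                           prune_len_mm=config.prune_len_mm))
    field = DistanceField.from_mask(mask)
    lines = connect_and_extend(lines, field, adjacency=adjacency,
                               max_bridge_mm=config.max_bridge_mm)
    return [refine_with_lumen(ln, mask) for ln in lines]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full two-phase reconstruction and write all outputs.

    Deterministic for a fixed config and seed. Stage failures raise
    :class:`ComputeError` naming the stage; outputs written before the
    failure are retained.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    if not config.inputs and config.oracle_mask is None:
        raise ConfigError("pipeline needs at least one input sequence "
                          "or an oracle mask")
    volumes = {kind: aio.read_volume(path, kind)
               for kind, path in config.inputs.items()}
    if volumes:
        available = set(volumes)
        if not (available & set(BLACK_BLOOD)) and "TOF" in available:
            log.info("no black-blood sequence: falling back to the "
                     "bright-blood (TOF) path only")

    mask = _segment_phase(config, volumes)
    mask_path = out_dir / "vessel_mask.nii.gz"
    aio.write_mask(mask, mask_path)
    outputs["mask"] = str(mask_path)

    lines = _centerline_phase(config, mask)
    json_path = out_dir / "centerlines.json"
    aio.write_centerlines_json(lines, json_path)
    outputs["centerlines_json"] = str(json_path)
    vtk_path = out_dir / "centerlines.vtk"
    aio.write_centerlines_vtk(lines, vtk_path)
    outputs["centerlines_vtk"] = str(vtk_path)

    # CPR per reconstructed artery
    cpr_kind = config.cpr_sequence
    if cpr_kind is None:
        cpr_kind = next((k for k in BLACK_BLOOD if k in volumes),
                        "TOF" if "TOF" in volumes else None)
    if cpr_kind and cpr_kind in volumes:
        vol = volumes[cpr_kind]
        for i, ln in enumerate(lines):
            if ln.n_points < 2 or ln.length == 0:
                continue
            try:
                img = straightened_cpr(
                    vol, ln, half_width_mm=config.cpr_half_width_mm,
                    step_mm=config.cpr_step_mm, angle_deg=config.cpr_angle_deg)
            except ValueError as exc:
                warnings.warn(f"CPR skipped for {ln.label}/{ln.side}: {exc}")
                continue
            stem = f"cpr_{ln.label}_{ln.side}_{i}"
            png = out_dir / f"{stem}.png"
            aio.write_cpr_png(img.pixels, png)
            outputs[f"{stem}.png"] = str(png)
            nii = out_dir / f"{stem}.nii.gz"
            aio.write_volume(Volume3D(img.pixels[:, :, None],
                                      (img.along_spacing_mm,
                                       img.cross_spacing_mm, 1.0),
                                      cpr_kind), nii)
            outputs[f"{stem}.nii"] = str(nii)

    report = _metrics_report(config, mask, lines)
    if report is not None:
        rpt_path = out_dir / "metrics.json"
        with open(rpt_path, "w") as fh:
            json.dump(report, fh, indent=1)
        outputs["metrics"] = str(rpt_path)

    aio.write_provenance(out_dir / "provenance.json", config, config.seed)
    outputs["provenance"] = str(out_dir / "provenance.json")
    return PipelineResult(mask, lines, outputs, report)


def _metrics_report(config: PipelineConfig, mask: VesselMask,
                    lines: list[Centerline]) -> Optional[dict]:
    """Dice / centerline accuracy / MCD / rubric against supplied truth."""
    report: dict = {}
    truth_mask = None
    if config.truth_mask:
        truth_mask = aio.read_mask(config.truth_mask)
        report["dice"] = evaluate_masks(mask.data, truth_mask.data, LABEL_VALUES)
    if config.truth_centerlines:
        truth_lines = aio.read_centerlines_json(config.truth_centerlines)
        per_line = []
        for truth in truth_lines:
            match = [ln for ln in lines
                     if ln.label == truth.label and ln.side == truth.side]
            if not match:       # side estimation can disagree near the midline
                match = [ln for ln in lines if ln.label == truth.label]
            if not match:
                per_line.append({"label": truth.label, "side": truth.side,
                                 "found": False})
                continue
            best = min(match, key=lambda ln: mcd(truth, ln))
            entry = {
                "label": truth.label, "side": truth.side, "found": True,
                "mcd_mm": mcd(truth, best),
                "centerline_accuracy": centerline_accuracy(
                    best, truth, tol_mm=config.tol_mm),
            }
            if truth_mask is not None:
                dev = deviation_fraction(best, truth_mask)
                entry["deviation_fraction"] = dev
                entry["rubric_score"] = rubric_score(dev, True)
            per_line.append(entry)
        report["centerlines"] = per_line
    return report or None
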