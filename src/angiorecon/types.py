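"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Arrays are indexed ``[x, y, z]``; the x axis crosses the mid-sagittal
  plane (left/right), z runs inferior -> superior.
* World coordinates are axis-aligned millimetres with 0-based voxel
  centres: ``world = index * spacing``.
* Arteries are labelled 1..8 in the fixed order of :data:`ARTERY_LABELS`;
  0 is background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The eight head-and-neck arteries the pipeline recognises.
ARTERY_LABELS: tuple[str, ...] = (
    "CCA", "ICA", "ECA", "ACA", "MCA", "VA", "BA", "PCA",
)

#: Integer value of each artery label in a mask (background = 0).
LABEL_VALUES: dict[str, int] = {name: i + 1 for i, name in enumerate(ARTERY_LABELS)}
VALUE_LABELS: dict[int, str] = {v: k for k, v in LABEL_VALUES.items()}

#: Recognised MR sequence kinds.
SEQUENCE_KINDS: tuple[str, ...] = ("T1WI", "T1WI-CE", "TOF")

#: Black-blood sequences (dark lumen, visible wall).
BLACK_BLOOD: tuple[str, ...] = ("T1WI", "T1WI-CE")

SIDES = ("left", "right", "midline")


@dataclass
class Volume3D:
    """A scalar 3D image grid with isotropic-or-not voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    kind: str = "T1WI"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_extent(self) -> np.ndarray:
        """World coordinate of the last voxel centre per axis (mm)."""
        return (np.array(self.shape) - 1) * np.array(self.spacing)

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing, self.kind)


@dataclass
class VesselMask:
    """Integer label grid: 0 = background, 1..8 = arteries per LABEL_VALUES."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VesselMask requires a 3D array")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("VesselMask data must be an integer array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels_present(self) -> list[str]:
        values = np.unique(self.data)
        return [VALUE_LABELS[int(v)] for v in values if int(v) in VALUE_LABELS]

    def binary(self, label: Optional[str] = None) -> np.ndarray:
        """Boolean grid of one artery label, or of all foreground."""
        if label is None:
            return self.data > 0
        return self.data == LABEL_VALUES[label]

    def copy(self) -> "VesselMask":
        return VesselMask(self.data.copy(), self.spacing)


@dataclass
class Centerline:
    """An ordered polyline through a vessel lumen, in world millimetres.

    ``flags`` marks special point ranges: ``bridged`` spans were filled in
    by path tracing across a gap (e.g. an occlusion) rather than taken
    from the segmentation, and are exempt from lumen-based re-centring.
    """

    points: np.ndarray
    label: str
    side: str = "midline"
    bridged: list[tuple[int, int]] = field(default_factory=list)
    complete: bool = True

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ValueError("Centerline requires an (N, 3) array with N >= 1")
        if self.label not in ARTERY_LABELS:
            raise ValueError(f"unknown artery label {self.label!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length per point (mm), starting at 0."""
        if self.n_points == 1:
            return np.zeros(1)
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def resample(self, step_mm: float) -> "Centerline":
        """Uniform arc-length resampling at ``step_mm`` (endpoints kept)."""
        if step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.n_points == 1 or self.length == 0:
            return Centerline(self.points[:1].copy(), self.label, self.side,
                              complete=self.complete)
        s = self.arc_length
        n = max(int(np.ceil(self.length / step_mm)), 1)
        targets = np.linspace(0.0, self.length, n + 1)
        pts = np.column_stack([np.interp(targets, s, self.points[:, a])
                               for a in range(3)])
        return Centerline(pts, self.label, self.side, complete=self.complete)

    def copy(self) -> "Centerline":
        return Centerline(self.points.copy(), self.label, self.side,
                          bridged=list(self.bridged), complete=self.complete)


def resample_polyline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Uniform arc-length resampling of a raw (N, 3) polyline."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        return points.copy()
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    total = s[-1]
    if total == 0:
        return points[:1].copy()
    n = max(int(np.ceil(total / step_mm)), 1)
    targets = np.linspace(0.0, total, n + 1)
    return np.column_stack([np.interp(targets, s, points[:, a]) for a in range(3)])
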