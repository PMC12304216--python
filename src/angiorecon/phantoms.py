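"""Synthetic multi-sequence vascular phantoms and training augmentation.

Clinical 3D MR vessel-wall imaging pairs bright-blood TOF angiography
(flowing blood bright, delineating the patent lumen) with black-blood
T1-weighted sequences (lumen dark, wall and thrombus visible). Occluded
segments vanish from TOF but remain traceable on black-blood images.
This module emulates exactly that contrast behaviour on parametric
tubular trees, with ground-truth masks and centerlines, so the
segmentation network and the geometry pipeline can be exercised and
measured without clinical data.

The augmentation suite mirrors the training-set expansion used for the
segmentation model: displacement, truncation (field-of-view crop),
left-right reversal, and simulated occlusion, which together with one
composed operation yield a six-fold increase per input sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .types import (ARTERY_LABELS, BLACK_BLOOD, LABEL_VALUES, SEQUENCE_KINDS,
                    SIDES, Centerline, VesselMask, Volume3D)

__all__ = [
    "Branch", "PhantomSpec", "PhantomSample", "AugmentConfig",
    "generate_phantom", "augment",
    "straight_tube_spec", "y_bifurcation_spec", "occluded_tube_spec",
    "bilateral_spec", "random_phantom_spec",
]

# Default per-sequence intensity model (arbitrary MR units). TOF shows a
# bright lumen on a dark background; black-blood sequences show a dark
# lumen on mid-grey tissue. An occluded span drops to background on TOF
# (no flow signal) but takes a distinct bright, thrombus/enhancement-like
# value on T1WI / T1WI-CE so the path stays traceable there.
DEFAULT_BACKGROUND = {"T1WI": 120.0, "T1WI-CE": 120.0, "TOF": 30.0}
DEFAULT_LUMEN = {"T1WI": 40.0, "T1WI-CE": 40.0, "TOF": 240.0}
DEFAULT_OCCLUDED = {"T1WI": 200.0, "T1WI-CE": 220.0, "TOF": 30.0}
DEFAULT_NOISE = {"T1WI": 5.0, "T1WI-CE": 5.0, "TOF": 5.0}


@dataclass
class Branch:
    """One tubular vessel segment of a phantom tree."""

    label: str
    control_points: np.ndarray          # (K, 3) world mm, K >= 2
    radius_mm: np.ndarray               # (K,) per-control-point radius
    side: str = "midline"
    occlusion_span: Optional[tuple[float, float]] = None   # arc-length mm

    def __post_init__(self) -> None:
        if self.label not in ARTERY_LABELS:
            raise ValueError(f"unknown artery label {self.label!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        self.control_points = np.atleast_2d(
            np.asarray(self.control_points, dtype=float))
        if self.control_points.shape[0] < 2 or self.control_points.shape[1] != 3:
            raise ValueError("control_points must be (K>=2, 3)")
        self.radius_mm = np.broadcast_to(
            np.asarray(self.radius_mm, dtype=float),
            (self.control_points.shape[0],)).copy()
        if np.any(self.radius_mm <= 0):
            raise ValueError(f"branch {self.label}: radii must be positive")


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic vascular phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    branches: list[Branch] = field(default_factory=list)
    noise_sigma: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))
    background_level: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND))
    lumen_level: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LUMEN))
    occluded_level: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCLUDED))
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(n < 16 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 16 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if any(v < 0 for v in self.noise_sigma.values()):
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomSample:
    """A rendered phantom: multi-sequence volumes + ground truth."""

    volumes: dict[str, Volume3D]
    mask: VesselMask
    centerlines: list[Centerline]
    occluded: np.ndarray                 # bool grid: lumen voxels occluded on TOF

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.mask.spacing

    def copy(self) -> "PhantomSample":
        return PhantomSample(
            {k: v.copy() for k, v in self.volumes.items()},
            self.mask.copy(),
            [c.copy() for c in self.centerlines],
            self.occluded.copy(),
        )


def _branch_curve(branch: Branch, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Smooth curve through the control points, arc-length resampled.

    Returns (points (N,3), radii (N,)). Cubic interpolation when there
    are >= 3 control points, chord otherwise.
    """
    cp = branch.control_points
    chord = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(cp, axis=0), axis=1))])
    if chord[-1] == 0:
        raise ValueError(f"branch {branch.label}: degenerate control points")
    if cp.shape[0] >= 3:
        spline = CubicSpline(chord, cp, axis=0)
        dense_t = np.linspace(0.0, chord[-1], max(4 * cp.shape[0], 64))
        dense = spline(dense_t)
    else:
        dense_t = chord
        dense = cp
    # arc-length reparameterisation of the dense polyline
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(s[-1] / step_mm)), 1)
    targets = np.linspace(0.0, s[-1], n + 1)
    pts = np.column_stack([np.interp(targets, s, dense[:, a]) for a in range(3)])
    # map arc length back to chord parameter to interpolate radii
    chord_at = np.interp(targets, s, dense_t)
    radii = np.interp(chord_at, chord, branch.radius_mm)
    return pts, radii


def _rasterize_branch(points: np.ndarray, radii: np.ndarray,
                      shape: tuple[int, int, int],
                      spacing: tuple[float, float, float]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Voxels within the tube, plus each lumen voxel's nearest arc index."""
    sp = np.asarray(spacing)
    extent = (np.asarray(shape) - 1) * sp
    rmax = float(radii.max())
    lo = points.min(axis=0) - rmax
    hi = points.max(axis=0) + rmax
    ilo = np.maximum(np.floor(lo / sp).astype(int), 0)
    ihi = np.minimum(np.ceil(hi / sp).astype(int), np.asarray(shape) - 1)
    grids = np.meshgrid(*[np.arange(ilo[a], ihi[a] + 1) for a in range(3)],
                        indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    world = idx * sp
    tree = cKDTree(points)
    dist, nearest = tree.query(world)
    inside = dist <= radii[nearest]
    # flat end caps: drop voxels projecting beyond the curve's endpoints
    if len(points) >= 2:
        t0 = points[1] - points[0]
        t0 /= np.linalg.norm(t0)
        t1 = points[-1] - points[-2]
        t1 /= np.linalg.norm(t1)
        at_start = nearest == 0
        inside[at_start] &= (world[at_start] - points[0]) @ t0 >= 0.0
        at_end = nearest == len(points) - 1
        inside[at_end] &= (world[at_end] - points[-1]) @ t1 <= 0.0
    lumen = np.zeros(shape, dtype=bool)
    arc_idx = np.full(shape, -1, dtype=np.int32)
    sel = idx[inside]
    lumen[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    arc_idx[sel[:, 0], sel[:, 1], sel[:, 2]] = nearest[inside]
    return lumen, arc_idx


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render a phantom spec into multi-sequence volumes + ground truth.

    Deterministic: identical spec (including seed) gives bit-identical
    output. Raises if a branch leaves the grid or two branches with
    different labels overlap (the ground truth must be unambiguous).
    """
    if not spec.branches:
        raise ValueError("phantom spec has no branches")
    shape = spec.grid_shape
    sp = np.asarray(spec.spacing_mm)
    extent = (np.asarray(shape) - 1) * sp
    step = 0.25 * float(min(spec.spacing_mm))

    mask = np.zeros(shape, dtype=np.uint8)
    occluded = np.zeros(shape, dtype=bool)
    centerlines: list[Centerline] = []
    # per-branch lumen painting with overlap bookkeeping
    for branch in spec.branches:
        points, radii = _branch_curve(branch, step)
        # tube cross-sections are disks perpendicular to the tangent (flat
        # end caps), so the per-axis half-extent is r*sqrt(1 - t_axis^2)
        tangents = np.gradient(points, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        half = radii[:, None] * np.sqrt(np.clip(1.0 - tangents**2, 0.0, 1.0))
        if np.any(points - half < -1e-9) or np.any(points + half > extent + 1e-9):
            raise ValueError(
                f"branch {branch.label} ({branch.side}) exits the grid")
        lumen, arc_idx = _rasterize_branch(points, radii, shape, spec.spacing_mm)
        value = LABEL_VALUES[branch.label]
        clash = lumen & (mask != 0) & (mask != value)
        if clash.any():
            other = VesselMask(mask, spec.spacing_mm).labels_present()
            raise ValueError(
                f"branch {branch.label} overlaps a branch of a different label "
                f"(labels present: {other})")
        mask[lumen] = value
        if branch.occlusion_span is not None:
            s0, s1 = branch.occlusion_span
            arc = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(points, axis=0), axis=1))])
            if not (0.0 <= s0 < s1 <= arc[-1] + 1e-9):
                raise ValueError(
                    f"branch {branch.label}: occlusion_span {branch.occlusion_span} "
                    f"outside arc length [0, {arc[-1]:.2f}]")
            in_span = np.zeros(len(points), dtype=bool)
            in_span[(arc >= s0) & (arc <= s1)] = True
            span_vox = lumen & in_span[np.clip(arc_idx, 0, len(points) - 1)]
            occluded |= span_vox
        centerlines.append(Centerline(points, branch.label, branch.side))

    rng_streams = {kind: np.random.default_rng(s) for kind, s in zip(
        SEQUENCE_KINDS, np.random.SeedSequence(spec.seed).spawn(len(SEQUENCE_KINDS)))}
    volumes: dict[str, Volume3D] = {}
    fg = mask > 0
    for kind in SEQUENCE_KINDS:
        vol = np.full(shape, spec.background_level[kind], dtype=np.float32)
        vol[fg] = spec.lumen_level[kind]
        vol[occluded] = spec.occluded_level[kind]
        sigma = spec.noise_sigma.get(kind, 0.0)
        if sigma > 0:
            vol = vol + rng_streams[kind].normal(
                0.0, sigma, size=shape).astype(np.float32)
        volumes[kind] = Volume3D(vol.astype(np.float32), spec.spacing_mm, kind)

    return PhantomSample(volumes, VesselMask(mask, spec.spacing_mm),
                         centerlines, occluded)


# ---------------------------------------------------------------------------
# Canonical phantom specs used throughout tests, docs and evaluation.
# ---------------------------------------------------------------------------

def straight_tube_spec(label: str = "CCA", radius_mm: float = 3.0,
                       length_mm: float = 40.0, grid: int = 64,
                       spacing: float = 1.0, axis: int = 2,
                       noise: float = 0.0, seed: int = 0,
                       offset: Optional[tuple[float, float, float]] = None
                       ) -> PhantomSpec:
    """A single straight axis-aligned tube centred on a voxel centre."""
    centre = round((grid - 1) / 2.0) * spacing
    if offset is None:
        offset = (centre, centre, centre)
    lo = centre - length_mm / 2.0
    hi = centre + length_mm / 2.0
    p0 = np.array(offset, dtype=float)
    p1 = p0.copy()
    p0[axis] = lo
    p1[axis] = hi
    mid_x = (grid - 1) * spacing / 2.0
    mean_x = 0.5 * (p0[0] + p1[0])
    side = ("left" if mean_x > mid_x + 0.5 * spacing
            else "right" if mean_x < mid_x - 0.5 * spacing else "midline")
    branch = Branch(label, np.stack([p0, p1]), radius_mm, side=side)
    return PhantomSpec(grid_shape=(grid,) * 3, spacing_mm=(spacing,) * 3,
                       branches=[branch],
                       noise_sigma={k: noise for k in SEQUENCE_KINDS}, seed=seed)


def occluded_tube_spec(label: str = "ICA", radius_mm: float = 3.0,
                       length_mm: float = 44.0, gap_mm: float = 6.0,
                       grid: int = 64, spacing: float = 1.0,
                       noise: float = 0.0, seed: int = 0) -> PhantomSpec:
    """A straight tube whose middle ``gap_mm`` is occluded (dark on TOF)."""
    spec = straight_tube_spec(label, radius_mm, length_mm, grid, spacing,
                              noise=noise, seed=seed)
    mid = length_mm / 2.0
    spec.branches[0].occlusion_span = (mid - gap_mm / 2.0, mid + gap_mm / 2.0)
    return spec


def y_bifurcation_spec(grid: int = 64, spacing: float = 1.0,
                       radius_mm: float = 3.0, noise: float = 0.0,
                       seed: int = 0, same_label: bool = False) -> PhantomSpec:
    """A carotid-like Y: common trunk splitting into two daughters.

    ``same_label=True`` labels the whole Y as one artery (useful for
    junction-topology tests); otherwise trunk=CCA, daughters=ICA/ECA.
    """
    c = round((grid - 1) / 2.0) * spacing
    zs = np.array([0.15, 0.5, 0.85]) * (grid - 1) * spacing
    junction = np.array([c, c, zs[1]])
    trunk = np.array([[c, c, zs[0]], junction])
    d_ica = np.array([junction,
                      [c + 6.0, c, (zs[1] + zs[2]) / 2],
                      [c + 9.0, c, zs[2]]])
    d_eca = np.array([junction,
                      [c - 5.0, c, (zs[1] + zs[2]) / 2],
                      [c - 8.0, c, zs[2]]])
    if same_label:
        labels = ("ICA", "ICA", "ICA")
    else:
        # distinct labels must not overlap (the ground truth is
        # unambiguous), so the daughters start distal of the junction;
        # connect_and_extend later bridges these short junction gaps
        labels = ("CCA", "ICA", "ECA")
        for d, r in ((d_ica, 0.8 * radius_mm), (d_eca, 0.7 * radius_mm)):
            u = d[1] - d[0]
            u = u / np.linalg.norm(u)
            d[0] = junction + u * (radius_mm + r + 0.6 * spacing)
    branches = [
        Branch(labels[0], trunk, radius_mm, side="left"),
        Branch(labels[1], d_ica, radius_mm * 0.8, side="left"),
        Branch(labels[2], d_eca, radius_mm * 0.7, side="left"),
    ]
    return PhantomSpec(grid_shape=(grid,) * 3, spacing_mm=(spacing,) * 3,
                       branches=branches,
                       noise_sigma={k: noise for k in SEQUENCE_KINDS}, seed=seed)


def bilateral_spec(grid: int = 64, spacing: float = 1.0, noise: float = 5.0,
                   seed: int = 0) -> PhantomSpec:
    """Left/right carotid pair plus a midline basilar-like vessel."""
    e = (grid - 1) * spacing
    zlo, zhi = 0.12 * e, 0.88 * e
    left = Branch("ICA", np.array([[0.70 * e, 0.45 * e, zlo],
                                   [0.74 * e, 0.52 * e, 0.5 * e],
                                   [0.68 * e, 0.48 * e, zhi]]),
                  2.5, side="left")
    right = Branch("ICA", np.array([[0.30 * e, 0.45 * e, zlo],
                                    [0.26 * e, 0.52 * e, 0.5 * e],
                                    [0.32 * e, 0.48 * e, zhi]]),
                   2.5, side="right")
    mid = Branch("BA", np.array([[0.5 * e, 0.68 * e, 0.30 * e],
                                 [0.5 * e, 0.70 * e, zhi]]),
                 2.0, side="midline")
    return PhantomSpec(grid_shape=(grid,) * 3, spacing_mm=(spacing,) * 3,
                       branches=[left, right, mid],
                       noise_sigma={k: noise for k in SEQUENCE_KINDS}, seed=seed)


def random_phantom_spec(seed: int, grid: int = 64, spacing: float = 1.0,
                        noise: float = 5.0, n_branches: int = 2,
                        occlusion_prob: float = 0.3) -> PhantomSpec:
    """A randomised curved-tube phantom for training-set generation.

    Draws gently curved, roughly vertical tubes with jittered position,
    curvature and radius, occasionally occluded — emulating the
    variability (and the occlusion cases) of a clinical training set.
    """
    rng = np.random.default_rng(seed)
    e = (grid - 1) * spacing
    branches = []
    labels = ["ICA", "ICA", "BA"]
    xs = [0.68, 0.32, 0.5]
    sides = ["left", "right", "midline"]
    for b in range(min(n_branches, 3)):
        x0 = xs[b] * e + rng.uniform(-0.05, 0.05) * e
        y0 = 0.5 * e + rng.uniform(-0.1, 0.1) * e
        zlo = rng.uniform(0.08, 0.18) * e
        zhi = rng.uniform(0.82, 0.92) * e
        bow = rng.uniform(-0.08, 0.08, size=2) * e
        cp = np.array([[x0, y0, zlo],
                       [x0 + bow[0], y0 + bow[1], 0.5 * (zlo + zhi)],
                       [x0 + rng.uniform(-0.04, 0.04) * e,
                        y0 + rng.uniform(-0.04, 0.04) * e, zhi]])
        radius = rng.uniform(2.0, 3.2)
        occ = None
        if rng.random() < occlusion_prob:
            length = zhi - zlo
            span_len = rng.uniform(4.0, 8.0)
            start = rng.uniform(0.2, 0.7) * length
            occ = (start, min(start + span_len, 0.95 * length))
        branches.append(Branch(labels[b], cp, radius, side=sides[b],
                               occlusion_span=occ))
    return PhantomSpec(grid_shape=(grid,) * 3, spacing_mm=(spacing,) * 3,
                       branches=branches,
                       noise_sigma={k: noise for k in SEQUENCE_KINDS},
                       seed=int(rng.integers(0, 2**31 - 1)))


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Training augmentation settings.

    The default configuration emits, per input sample: the original,
    one displaced, one truncated, one left-right reversed, one with a
    simulated occlusion, and one displaced-and-reversed composition —
    six samples in total.
    """

    displacement: bool = True
    truncation: bool = True
    flip: bool = True
    occlusion: bool = True
    compose_displacement_flip: bool = True
    displacement_voxels: Optional[tuple[int, int, int]] = None   # None = random
    max_shift_voxels: int = 8
    truncation_fraction: float = 0.75
    occlusion_length_mm: float = 6.0
    seed: int = 0


def _shift_volume(data: np.ndarray, shift: tuple[int, int, int],
                  fill: float) -> np.ndarray:
    out = np.full_like(data, fill)
    src = [slice(max(0, -s), data.shape[a] - max(0, s)) for a, s in enumerate(shift)]
    dst = [slice(max(0, s), data.shape[a] - max(0, -s)) for a, s in enumerate(shift)]
    out[tuple(dst)] = data[tuple(src)]
    return out


def _background_estimate(vol: Volume3D, mask: np.ndarray) -> float:
    bg = vol.data[~mask]
    if bg.size == 0:
        return float(vol.data.min())
    return float(np.median(bg))


def displace(sample: PhantomSample, shift: tuple[int, int, int]) -> PhantomSample:
    """Integer-voxel translation with background padding (paired transform)."""
    out = sample.copy()
    fg = sample.mask.data > 0
    for kind, vol in out.volumes.items():
        fill = _background_estimate(sample.volumes[kind], fg)
        vol.data = _shift_volume(vol.data, shift, fill)
    out.mask.data = _shift_volume(sample.mask.data, shift, 0)
    out.occluded = _shift_volume(sample.occluded, shift, False)
    delta = np.asarray(shift) * np.asarray(sample.spacing)
    for line in out.centerlines:
        line.points = line.points + delta
    return out


def truncate(sample: PhantomSample, origin: tuple[int, int, int],
             size: tuple[int, int, int]) -> PhantomSample:
    """Crop the field of view to a window; centerlines are cropped too."""
    sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
    vols = {k: Volume3D(np.ascontiguousarray(v.data[sl]), v.spacing, v.kind)
            for k, v in sample.volumes.items()}
    mask = VesselMask(np.ascontiguousarray(sample.mask.data[sl]), sample.spacing)
    occ = np.ascontiguousarray(sample.occluded[sl])
    sp = np.asarray(sample.spacing)
    lo = np.asarray(origin) * sp
    hi = (np.asarray(origin) + np.asarray(size) - 1) * sp
    lines = []
    for line in sample.centerlines:
        inside = np.all((line.points >= lo - 1e-9) &
                        (line.points <= hi + 1e-9), axis=1)
        if not inside.any():
            continue
        pts = line.points[inside] - lo
        lines.append(Centerline(pts, line.label, line.side,
                                complete=bool(inside.all())))
    return PhantomSample(vols, mask, lines, occ)


def flip_lr(sample: PhantomSample) -> PhantomSample:
    """Mirror across the mid-sagittal plane; left and right sides swap."""
    out = sample.copy()
    nx = sample.mask.shape[0]
    sx = sample.spacing[0]
    for vol in out.volumes.values():
        vol.data = np.ascontiguousarray(vol.data[::-1])
    out.mask.data = np.ascontiguousarray(out.mask.data[::-1])
    out.occluded = np.ascontiguousarray(out.occluded[::-1])
    swap = {"left": "right", "right": "left", "midline": "midline"}
    for line in out.centerlines:
        line.points = line.points.copy()
        line.points[:, 0] = (nx - 1) * sx - line.points[:, 0]
        line.side = swap[line.side]
    return out


def simulate_occlusion(sample: PhantomSample, rng: np.random.Generator,
                       length_mm: float) -> PhantomSample:
    """Suppress the TOF lumen signal over a random arc span of one branch.

    The black-blood volumes and the mask are untouched: the occluded
    stretch stays delineated there, as in real disease.
    """
    out = sample.copy()
    if not sample.centerlines or "TOF" not in sample.volumes:
        return out
    k = int(rng.integers(0, len(sample.centerlines)))
    line = sample.centerlines[k]
    total = line.length
    span_len = min(length_mm, 0.8 * total)
    start = float(rng.uniform(0.0, max(total - span_len, 1e-6)))
    arc = line.arc_length
    in_span = (arc >= start) & (arc <= start + span_len)
    if not in_span.any():
        return out
    span_pts = line.points[in_span]
    lumen = sample.mask.binary(line.label)
    vox = np.argwhere(lumen)
    if vox.size == 0:
        return out
    world = vox * np.asarray(sample.spacing)
    d_span = cKDTree(span_pts).query(world)[0]
    d_line = cKDTree(line.points).query(world)[0]
    hit = vox[(d_span <= d_line + 1e-9)]
    tof = out.volumes["TOF"]
    fill = _background_estimate(sample.volumes["TOF"], sample.mask.data > 0)
    tof.data[hit[:, 0], hit[:, 1], hit[:, 2]] = fill
    out.occluded[hit[:, 0], hit[:, 1], hit[:, 2]] = True
    return out


def augment(sample: PhantomSample, config: AugmentConfig | None = None
            ) -> list[PhantomSample]:
    """Expand one sample into an augmented training set.

    With the default config the output is exactly six samples: the
    original plus displacement, truncation, left-right reversal,
    simulated occlusion, and a displacement∘flip composition.
    """
    config = config or AugmentConfig()
    rng = np.random.default_rng(config.seed)
    out = [sample.copy()]

    def draw_shift() -> tuple[int, int, int]:
        if config.displacement_voxels is not None:
            return tuple(int(v) for v in config.displacement_voxels)
        m = config.max_shift_voxels
        s = rng.integers(-m, m + 1, size=3)
        if not s.any():
            s[0] = m
        return tuple(int(v) for v in s)

    if config.displacement:
        out.append(displace(sample, draw_shift()))
    if config.truncation:
        shape = np.asarray(sample.mask.shape)
        size = np.maximum((shape * config.truncation_fraction).astype(int), 16)
        placed = None
        for _ in range(20):
            origin = tuple(int(rng.integers(0, shape[a] - size[a] + 1))
                           for a in range(3))
            window = tuple(slice(o, o + s) for o, s in zip(origin, size))
            if sample.mask.data[window].any():
                placed = truncate(sample, origin, tuple(int(v) for v in size))
                break
            warnings.warn("truncation window empty of vessel; re-drawing")
        if placed is None:
            # final fallback: window centred on the vessel bounding box
            vox = np.argwhere(sample.mask.data > 0)
            centre = vox.mean(axis=0).astype(int)
            origin = tuple(int(np.clip(centre[a] - size[a] // 2, 0,
                                       shape[a] - size[a])) for a in range(3))
            placed = truncate(sample, origin, tuple(int(v) for v in size))
        out.append(placed)
    if config.flip:
        out.append(flip_lr(sample))
    if config.occlusion:
        out.append(simulate_occlusion(sample, rng, config.occlusion_length_mm))
    if config.compose_displacement_flip:
        out.append(flip_lr(displace(sample, draw_shift())))
    return out
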