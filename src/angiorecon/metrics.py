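"""Evaluation metrics for segmentation masks and centerlines.

Three quantities drive evaluation throughout the pipeline:

* ``dice`` — volumetric overlap ``2|X ∩ X̄| / (|X| + |X̄|)`` between a
  predicted and an annotated voxel set.
* ``centerline_accuracy`` — the fraction of the ground-truth centerline
  length that the extraction recovered, operationalised as the arc length
  of the extracted line lying within a distance tolerance of the truth
  polyline, divided by the truth arc length (capped at 1).
* ``mcd`` — mean centerline distance: the symmetric average of the two
  directed mean nearest-neighbour point distances between the predicted
  and annotated centerline point sets, in millimetres.
"""

from __future__ import annotations

import warnings
from typing import Union

import numpy as np
from scipy.spatial import cKDTree

from .types import Centerline, resample_polyline

__all__ = ["dice", "mcd", "centerline_accuracy", "hausdorff"]

PointsLike = Union[np.ndarray, Centerline]


def _as_bool_grid(x) -> np.ndarray:
    arr = np.asarray(x)
    return arr.astype(bool)


def dice(X, Xbar) -> float:
    """Dice coefficient between two voxel sets on the same grid.

    Accepts boolean grids (or anything castable). Both sets empty is
    defined as perfect agreement (1.0). Mismatched grids are an error,
    never silently broadcast.
    """
    a = _as_bool_grid(X)
    b = _as_bool_grid(Xbar)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def _points_of(obj: PointsLike, resample_mm: float | None) -> np.ndarray:
    if isinstance(obj, Centerline):
        pts = obj.points
    else:
        pts = np.atleast_2d(np.asarray(obj, dtype=float))
    if pts.size == 0:
        raise ValueError("empty point set")
    if pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if resample_mm is not None and pts.shape[0] >= 2:
        pts = resample_polyline(pts, resample_mm)
    return pts


def mcd(S_G: PointsLike, S_P: PointsLike, resample_mm: float | None = 0.5) -> float:
    """Mean centerline distance (mm) between two point sets.

    ``0.5 * (mean_i min_j d(g_i, p_j) + mean_j min_i d(p_j, g_i))`` with
    Euclidean ``d``. Polyline inputs are arc-length resampled at
    ``resample_mm`` first (pass ``None`` to evaluate raw points) so the
    value does not depend on annotation point density.
    """
    g = _points_of(S_G, resample_mm)
    p = _points_of(S_P, resample_mm)
    d_gp = cKDTree(p).query(g)[0]
    d_pg = cKDTree(g).query(p)[0]
    return 0.5 * (float(d_gp.mean()) + float(d_pg.mean()))


def hausdorff(S_G: PointsLike, S_P: PointsLike, resample_mm: float | None = 0.5) -> float:
    """Symmetric Hausdorff distance (mm) between two point sets (extra metric)."""
    g = _points_of(S_G, resample_mm)
    p = _points_of(S_P, resample_mm)
    d_gp = cKDTree(p).query(g)[0]
    d_pg = cKDTree(g).query(p)[0]
    return max(float(d_gp.max()), float(d_pg.max()))


def _point_to_segments_dist(points: np.ndarray, seg_a: np.ndarray,
                            seg_b: np.ndarray) -> np.ndarray:
    """Min distance of each point to any segment [a_i, b_i] (vectorised)."""
    ab = seg_b - seg_a                       # (M, 3)
    ab2 = np.einsum("ij,ij->i", ab, ab)      # (M,)
    ab2 = np.where(ab2 == 0, 1.0, ab2)
    ap = points[:, None, :] - seg_a[None, :, :]          # (N, M, 3)
    t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / ab2, 0.0, 1.0)
    closest = seg_a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def centerline_accuracy(extracted: PointsLike, truth: PointsLike,
                        tol_mm: float = 1.0, sample_mm: float = 0.1) -> float:
    """Fraction of the truth centerline length that was accurately extracted.

    The extracted polyline is sampled every ``sample_mm`` of arc length;
    each sample within ``tol_mm`` of the truth polyline contributes its
    arc-length weight. The accumulated "accurately extracted" length is
    divided by the truth arc length and capped at 1.
    """
    ext = _points_of(extracted, None)
    tru = _points_of(truth, None)
    truth_len = float(np.linalg.norm(np.diff(tru, axis=0), axis=1).sum())
    if truth_len == 0:
        raise ValueError("zero-length truth centerline")
    if ext.shape[0] < 2:
        return 0.0
    ext_len = float(np.linalg.norm(np.diff(ext, axis=0), axis=1).sum())
    if ext_len == 0:
        return 0.0
    samples = resample_polyline(ext, sample_mm)
    weight = ext_len / (samples.shape[0] - 1)
    # midpoint samples of each sub-segment carry the length weight
    mids = 0.5 * (samples[:-1] + samples[1:])
    if tru.shape[0] == 1:
        d = np.linalg.norm(mids - tru[0], axis=1)
    else:
        d = _point_to_segments_dist(mids, tru[:-1], tru[1:])
    good_len = float((d <= tol_mm).sum()) * weight
    return min(good_len / truth_len, 1.0)


def evaluate_masks(pred: np.ndarray, truth: np.ndarray,
                   labels: dict[str, int]) -> dict[str, float]:
    """Per-label Dice between two integer label grids."""
    if pred.shape != truth.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {truth.shape}")
    out = {}
    for name, value in labels.items():
        a = pred == value
        b = truth == value
        if not a.any() and not b.any():
            continue
        out[name] = dice(a, b)
    return out


def warn_empty(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
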