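"""Moving orthonormal frames along a polyline.

Frames are transported with the double-reflection (rotation-minimizing)
method: unlike the Frenet frame it is defined on straight segments and
never flips, which matters when resampling a volume around a vessel
centerline.
"""

from __future__ import annotations

import numpy as np

__all__ = ["polyline_tangents", "rotation_minimizing_frames"]


def polyline_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents per point via central differences (one-sided at ends)."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points for tangents")
    t = np.empty_like(points)
    t[0] = points[1] - points[0]
    t[-1] = points[-1] - points[-2]
    if n > 2:
        t[1:-1] = points[2:] - points[:-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return t / norms


def _initial_normal(t0: np.ndarray) -> np.ndarray:
    # pick the world axis least aligned with the tangent (deterministic)
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(t0)))] = 1.0
    n = axis - np.dot(axis, t0) * t0
    return n / np.linalg.norm(n)


def rotation_minimizing_frames(points: np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangent/normal/binormal per point, transported without twist.

    Double-reflection transport: each normal is reflected through the
    chord midplane and then through the new tangent's bisecting plane,
    which minimises rotation between consecutive frames.
    """
    points = np.asarray(points, dtype=float)
    tangents = polyline_tangents(points)
    n = points.shape[0]
    normals = np.empty_like(points)
    normals[0] = _initial_normal(tangents[0])
    for i in range(n - 1):
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-14:
            normals[i + 1] = normals[i]
            continue
        rL = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        tL = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - tL
        c2 = np.dot(v2, v2)
        if c2 < 1e-14:
            normals[i + 1] = rL
        else:
            normals[i + 1] = rL - (2.0 / c2) * np.dot(v2, rL) * v2
        # re-orthogonalise against accumulated numerical drift
        nrm = normals[i + 1] - np.dot(normals[i + 1], tangents[i + 1]) * tangents[i + 1]
        normals[i + 1] = nrm / np.linalg.norm(nrm)
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals
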