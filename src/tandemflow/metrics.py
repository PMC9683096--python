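"""Mesh-to-mesh distance measures (recovery error of restored vessels).

Exact point-to-triangle distances with a KD-tree candidate search; no
spatial-index dependency beyond scipy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .types import SurfaceMesh

__all__ = ["point_surface_distance", "symmetric_hausdorff"]


def _point_triangle_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Distance from each point p[i] to its triangle (a[i], b[i], c[i]).

    Vectorised Eberly closest-point-on-triangle: minimise the quadratic
    |a + s(b-a) + t(c-a) - p|^2 over the triangle s,t >= 0, s+t <= 1 by
    projecting the unconstrained optimum back onto the edges.
    """
    E0 = b - a
    E1 = c - a
    D = a - p
    aa = np.einsum("ij,ij->i", E0, E0)
    bb = np.einsum("ij,ij->i", E0, E1)
    cc = np.einsum("ij,ij->i", E1, E1)
    dd = np.einsum("ij,ij->i", E0, D)
    ee = np.einsum("ij,ij->i", E1, D)
    det = aa * cc - bb * bb
    s = bb * ee - cc * dd
    t = bb * dd - aa * ee

    s_out = np.empty_like(aa)
    t_out = np.empty_like(aa)
    inside = (s + t <= det) & (s >= 0) & (t >= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_out = np.where(inside, s / det, 0.0)
        t_out = np.where(inside, t / det, 0.0)

        # region: clamp onto each edge and pick the best
        # edge a-b (t=0)
        s_ab = np.clip(-dd / aa, 0.0, 1.0)
        d_ab = aa * s_ab**2 + 2 * dd * s_ab
        # edge a-c (s=0)
        t_ac = np.clip(-ee / cc, 0.0, 1.0)
        d_ac = cc * t_ac**2 + 2 * ee * t_ac
        # edge b-c (s+t=1): param u along c-b from b
        num = cc + ee - bb - dd
        den = aa - 2 * bb + cc
        u_bc = np.clip(num / den, 0.0, 1.0)
        s_bc = 1.0 - u_bc
        d_bc = (
            aa * s_bc**2 + cc * u_bc**2 + 2 * bb * s_bc * u_bc + 2 * dd * s_bc + 2 * ee * u_bc
        )
    best = np.argmin(np.stack([d_ab, d_ac, d_bc]), axis=0)
    s_edge = np.choose(best, [s_ab, np.zeros_like(s_ab), s_bc])
    t_edge = np.choose(best, [np.zeros_like(t_ac), t_ac, 1.0 - s_bc])
    s_out = np.where(inside, s_out, s_edge)
    t_out = np.where(inside, t_out, t_edge)
    closest = a + s_out[:, None] * E0 + t_out[:, None] * E1
    return np.linalg.norm(closest - p, axis=1)


def point_surface_distance(points: np.ndarray, mesh: SurfaceMesh, k_candidates: int = 24) -> np.ndarray:
    """Unsigned distance from each query point to the triangulated surface."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    cents = mesh.triangle_centroids()
    k = min(k_candidates, len(cents))
    _, cand = cKDTree(cents).query(points, k=k)
    cand = np.atleast_2d(cand)
    va, vb, vc = mesh.triangle_corners()
    out = np.full(len(points), np.inf)
    for col in range(cand.shape[1]):
        tri = cand[:, col]
        d = _point_triangle_distance(points, va[tri], vb[tri], vc[tri])
        out = np.minimum(out, d)
    return out


def symmetric_hausdorff(
    mesh_a: SurfaceMesh,
    mesh_b: SurfaceMesh,
    mask_a: np.ndarray | None = None,
    mask_b: np.ndarray | None = None,
) -> float:
    """max of the two directed vertex-to-surface Hausdorff distances,
    optionally restricted to vertex masks (e.g. the restored segment)."""
    pa = mesh_a.vertices if mask_a is None else mesh_a.vertices[mask_a]
    pb = mesh_b.vertices if mask_b is None else mesh_b.vertices[mask_b]
    d_ab = point_surface_distance(pa, mesh_b).max() if len(pa) else 0.0
    d_ba = point_surface_distance(pb, mesh_a).max() if len(pb) else 0.0
    return float(max(d_ab, d_ba))
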