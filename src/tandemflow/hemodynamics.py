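"""Wall-shear-stress indicator fields and Q-criterion vortex cores.

Surface indicators computed from a per-vertex WSS vector series tau(t)
sampled uniformly over one cardiac cycle of period T:

  TAWSS = (1/T) \int_0^T |tau| dt
      time-averaged WSS magnitude; low TAWSS marks stagnant wall regions.
  AFI(t) = tau(t) . tau_av / (|tau(t)| |tau_av|)
      aneurysm formation index: cosine of the angle between the
      instantaneous and cycle-averaged WSS vectors; -1 means full
      reversal of the wall traction direction.
  GON = 1 - |\int_0^T G dt| / \int_0^T |G| dt
      gradient oscillatory number, with G = (d f_p / dp, d f_q / dq) the
      diagonal in-surface gradient of the WSS components (f_p, f_q) in a
      fixed per-vertex tangent frame (p, q); GON in [0, 1] quantifies
      oscillating tension/compression on the wall.

The oscillatory shear index is deliberately not provided: it is strongly
collinear with AFI and adds no independent signal to the voting stage.

Volume analysis uses Q = 1/2 (|Omega|^2 - |S|^2) (Frobenius norms of the
spin and strain-rate tensors): Q > 0 where rotation dominates strain.
Vortex cores are face-connected components of tetrahedra above a fixed
fraction (default 8%) of the positive peak Q at peak systole.

All time integrals use the trapezoidal rule on the periodically extended
series, which for uniform sampling over a full cycle reduces to the
plain sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .types import RoiPatch, SurfaceMesh, ValidationError, VolumeField, WssSeries

__all__ = [
    "ScalarSurfaceField",
    "TangentFrameSet",
    "QField",
    "VortexCoreSet",
    "tawss",
    "afi",
    "min_afi",
    "tangent_frames",
    "gon",
    "q_field",
    "extract_vortex_cores",
    "core_roi_proximity",
]

_EPS_PRODUCT = 1e-12  # |tau_i||tau_av| below this -> AFI forced to 1, flagged
_EPS_DENOM = 1e-14  # GON denominator floor
_Q_FLOOR_REL = 1e-12  # positive-Q floor relative to the velocity-gradient scale


@dataclass
class ScalarSurfaceField:
    mesh: SurfaceMesh
    values: np.ndarray
    name: str
    flagged: np.ndarray | None = None  # vertices where a degenerate rule fired

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mesh.vertices),):
            raise ValidationError("field length must match mesh vertices")
        if not np.isfinite(self.values).all():
            raise ValidationError(f"{self.name}: non-finite values")


@dataclass
class TangentFrameSet:
    """Per-vertex orthonormal frame (p, q, n); p x q = n."""

    mesh: SurfaceMesh
    p: np.ndarray
    q: np.ndarray
    n: np.ndarray


def _cycle_mean(series: np.ndarray) -> np.ndarray:
    """Trapezoidal mean over the periodically extended uniform series."""
    return series.mean(axis=0)


def tawss(series: WssSeries) -> ScalarSurfaceField:
    """Time-averaged WSS magnitude (Pa) per vertex."""
    mag = np.linalg.norm(series.tau, axis=2)
    return ScalarSurfaceField(series.mesh, _cycle_mean(mag), "TAWSS")


def _tau_av(series: WssSeries) -> np.ndarray:
    return _cycle_mean(series.tau)


def afi(series: WssSeries, time_index: int) -> ScalarSurfaceField:
    """Aneurysm formation index at one instant (e.g. mid-diastole)."""
    if not (0 <= time_index < series.n_times):
        raise ValidationError(f"time_index {time_index} out of range")
    tav = _tau_av(series)
    ti = series.tau[time_index]
    dot = np.einsum("ij,ij->i", ti, tav)
    prod = np.linalg.norm(ti, axis=1) * np.linalg.norm(tav, axis=1)
    degenerate = prod < _EPS_PRODUCT
    values = np.where(degenerate, 1.0, dot / np.where(degenerate, 1.0, prod))
    values = np.clip(values, -1.0, 1.0)
    return ScalarSurfaceField(series.mesh, values, "AFI", flagged=degenerate)


def min_afi(series: WssSeries) -> ScalarSurfaceField:
    """Pointwise minimum of AFI over the cycle (worst instantaneous reversal)."""
    tav = _tau_av(series)
    dot = np.einsum("tij,ij->ti", series.tau, tav)
    prod = np.linalg.norm(series.tau, axis=2) * np.linalg.norm(tav, axis=1)[None]
    degenerate = prod < _EPS_PRODUCT
    vals = np.where(degenerate, 1.0, dot / np.where(degenerate, 1.0, prod))
    out = np.clip(vals.min(axis=0), -1.0, 1.0)
    return ScalarSurfaceField(series.mesh, out, "AFI", flagged=degenerate.any(axis=0))


def tangent_frames(mesh: SurfaceMesh) -> TangentFrameSet:
    """Fixed per-vertex tangent frames for the (p, q) surface coordinates.

    n = area-weighted average of incident face normals; p = normalised
    tangential projection of a global reference axis (with a fallback
    when near-parallel); q = n x p.
    """
    nv = len(mesh.vertices)
    fn = mesh.triangle_normals() * mesh.triangle_areas()[:, None]
    n = np.zeros((nv, 3))
    for k in range(3):
        np.add.at(n, mesh.triangles[:, k], fn)
    norms = np.linalg.norm(n, axis=1)
    if (norms < 1e-30).any():
        raise ValidationError("vertex with zero-area star (no incident faces)")
    n /= norms[:, None]

    ref1 = np.array([1.0, 0.0, 0.0])
    ref2 = np.array([0.0, 1.0, 0.0])
    use2 = np.abs(n @ ref1) > 0.9
    ref = np.where(use2[:, None], ref2, ref1)
    p = ref - (np.einsum("ij,ij->i", n, ref))[:, None] * n
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    q = np.cross(n, p)
    return TangentFrameSet(mesh, p, q, n)


def _vertex_gradient(mesh: SurfaceMesh, f: np.ndarray, inv_cache: dict) -> np.ndarray:
    """Per-vertex 3D gradient of a vertex scalar field: per-face linear
    gradients, area-averaged onto vertices."""
    if "grad" not in inv_cache:
        a, b, c = mesh.triangle_corners()
        nrm = np.cross(b - a, c - a)
        areas2 = np.linalg.norm(nrm, axis=1)
        nhat = nrm / areas2[:, None]
        # gradient of barycentric hat functions on each face
        g0 = np.cross(nhat, c - b) / areas2[:, None]
        g1 = np.cross(nhat, a - c) / areas2[:, None]
        g2 = np.cross(nhat, b - a) / areas2[:, None]
        w = 0.5 * areas2  # face areas
        wsum = np.zeros(len(mesh.vertices))
        for k in range(3):
            np.add.at(wsum, mesh.triangles[:, k], w)
        inv_cache["grad"] = (g0, g1, g2, w, wsum)
    g0, g1, g2, w, wsum = inv_cache["grad"]
    t = mesh.triangles
    gf = f[t[:, 0], None] * g0 + f[t[:, 1], None] * g1 + f[t[:, 2], None] * g2
    out = np.zeros((len(mesh.vertices), 3))
    for k in range(3):
        np.add.at(out, t[:, k], gf * w[:, None])
    return out / wsum[:, None]


def gon(series: WssSeries, frames: TangentFrameSet | None = None) -> ScalarSurfaceField:
    """Gradient oscillatory number per vertex (dimensionless, in [0, 1])."""
    if frames is None:
        frames = tangent_frames(series.mesh)
    if frames.mesh is not series.mesh and len(frames.p) != len(series.mesh.vertices):
        raise ValidationError("tangent frames computed on a different mesh")
    cache: dict = {}
    nt, nv = series.n_times, len(series.mesh.vertices)
    G = np.empty((nt, nv, 2))
    for k in range(nt):
        tau_k = series.tau[k]
        fp = np.einsum("ij,ij->i", tau_k, frames.p)
        fq = np.einsum("ij,ij->i", tau_k, frames.q)
        G[k, :, 0] = np.einsum("ij,ij->i", _vertex_gradient(series.mesh, fp, cache), frames.p)
        G[k, :, 1] = np.einsum("ij,ij->i", _vertex_gradient(series.mesh, fq, cache), frames.q)
    num = np.linalg.norm(G.mean(axis=0), axis=1)
    den = np.linalg.norm(G, axis=2).mean(axis=0)
    degenerate = den < _EPS_DENOM
    values = np.where(degenerate, 0.0, 1.0 - num / np.where(degenerate, 1.0, den))
    values = np.clip(values, 0.0, 1.0)
    return ScalarSurfaceField(series.mesh, values, "GON", flagged=degenerate)


# ------------------------------------------------------------------ volume
@dataclass
class QField:
    """Per-tetrahedron Q-criterion values (1/s^2)."""

    volume: VolumeField
    q: np.ndarray
    gradient_scale: float  # max over tets of |S|^2 + |Omega|^2 (rounding floor)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.volume.tets),):
            raise ValidationError("q length must match tets")
        if not np.isfinite(self.q).all():
            raise ValidationError("non-finite Q values")


@dataclass
class VortexCoreSet:
    """Face-connected components of above-threshold tets, largest first."""

    volume: VolumeField
    components: list  # [{"tet_ids", "volume", "centroid"}]
    threshold_used: float
    time_index: int = 0

    def __len__(self):
        return len(self.components)


def q_field(volume: VolumeField) -> QField:
    """Q = 1/2 (|Omega|^2 - |S|^2) per tet from linear shape functions.

    The per-tet velocity gradient is exact for affine velocity fields, so
    solid rotation / shear / strain benchmarks hold to rounding error.
    """
    p = volume.points
    t = volume.tets
    E = np.stack([p[t[:, k]] - p[t[:, 0]] for k in (1, 2, 3)], axis=1)  # (nt,3edges,3xyz)
    dU = np.stack([volume.velocity[t[:, k]] - volume.velocity[t[:, 0]] for k in (1, 2, 3)], axis=1)
    try:
        # rows of E are edge vectors: E @ grad(u_i) = dU_i  =>  grad tensor
        Gt = np.linalg.solve(E, dU)  # (nt, 3, 3): Gt[e, j, i] = d u_i / d x_j
    except np.linalg.LinAlgError as exc:
        vols = volume.tet_volumes()
        bad = np.flatnonzero(vols < 1e-30)
        raise ValidationError(f"degenerate tet(s) at ids {bad[:10].tolist()}") from exc
    G = np.swapaxes(Gt, 1, 2)  # G[e, i, j] = d u_i / d x_j
    S = 0.5 * (G + np.swapaxes(G, 1, 2))
    W = 0.5 * (G - np.swapaxes(G, 1, 2))
    s2 = np.einsum("eij,eij->e", S, S)
    w2 = np.einsum("eij,eij->e", W, W)
    return QField(volume, 0.5 * (w2 - s2), gradient_scale=float((s2 + w2).max()))


def _tet_adjacency_components(tets: np.ndarray, selected: np.ndarray) -> list:
    """Connected components (shared triangular face) among selected tets."""
    sel = np.flatnonzero(selected)
    if len(sel) == 0:
        return []
    sub = tets[sel]
    faces = np.concatenate([sub[:, [1, 2, 3]], sub[:, [0, 2, 3]], sub[:, [0, 1, 3]], sub[:, [0, 1, 2]]])
    faces = np.sort(faces, axis=1)
    owner = np.tile(np.arange(len(sel)), 4)
    order = np.lexsort(faces.T[::-1])
    faces_sorted, owner_sorted = faces[order], owner[order]
    same = (faces_sorted[1:] == faces_sorted[:-1]).all(axis=1)
    i = owner_sorted[:-1][same]
    j = owner_sorted[1:][same]
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(len(sel), len(sel)))
    n_comp, labels = connected_components(adj, directed=False)
    return [sel[labels == c] for c in range(n_comp)]


def extract_vortex_cores(
    qf: QField,
    threshold_fraction: float = 0.08,
    peak_qfield: QField | None = None,
    time_index: int = 0,
) -> VortexCoreSet:
    """Binarise Q at a fraction of the positive peak and split into cores.

    The peak is taken from ``peak_qfield`` (the peak-systole instant) when
    given, so that one absolute threshold is applied across the cycle.
    Q values positive only at rounding level (relative to the
    velocity-gradient magnitude) are treated as non-positive; an empty
    core set is a valid result.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValidationError("threshold_fraction must be in (0, 1)")
    ref = peak_qfield if peak_qfield is not None else qf
    floor = _Q_FLOOR_REL * max(ref.gradient_scale, qf.gradient_scale)
    peak = ref.q.max(initial=0.0)
    if peak <= floor:
        return VortexCoreSet(qf.volume, [], threshold_used=float("nan"), time_index=time_index)
    threshold = threshold_fraction * peak
    comps = _tet_adjacency_components(qf.volume.tets, qf.q >= threshold)
    vols = qf.volume.tet_volumes()
    cents = qf.volume.tet_centroids()
    out = []
    for ids in comps:
        v = vols[ids]
        out.append(
            {
                "tet_ids": np.asarray(ids),
                "volume": float(v.sum()),
                "centroid": (cents[ids] * v[:, None]).sum(axis=0) / v.sum(),
            }
        )
    out.sort(key=lambda c: -c["volume"])
    return VortexCoreSet(qf.volume, out, threshold_used=float(threshold), time_index=time_index)


def core_roi_proximity(cores: VortexCoreSet, roi: RoiPatch, delta: float) -> list:
    """Distance of each vortex-core component to the ROI wall patch."""
    if len(cores) == 0:
        return []
    tree = cKDTree(roi.centroids())
    cents = cores.volume.tet_centroids()
    report = []
    for comp in cores.components:
        d, _ = tree.query(cents[comp["tet_ids"]])
        dist = float(np.min(d))
        report.append({"distance": dist, "near_roi": bool(dist <= delta), "volume": comp["volume"]})
    return report
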