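"""Core domain types shared by every stage of the tandem-aneurysm workflow.

Geometry is stored in the unit it was read in (clinical vessel meshes are
almost always millimetres); physical quantities (wall shear stress in Pa,
velocity in m/s) are SI.  ``Config.length_unit_scale`` carries the mm->m
factor used whenever geometry enters a physical formula.  All indices are
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "SurfaceMesh",
    "Centerline",
    "Plane",
    "CrossSection",
    "WssSeries",
    "VolumeField",
    "RoiPatch",
    "Config",
]


class ValidationError(ValueError):
    """An input violates a structural invariant (bad mesh, bad series...)."""


def _as_float_array(x, name: str, shape_tail: tuple) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 + len(shape_tail) or arr.shape[1:] != shape_tail:
        raise ValidationError(f"{name}: expected shape (n, {shape_tail}), got {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name}: non-finite values present")
    return arr


@dataclass
class SurfaceMesh:
    """Triangulated vessel-wall surface.

    vertices : (nv, 3) float array, mm by default
    triangles : (nt, 3) int array of vertex indices
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_normals: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = _as_float_array(self.vertices, "vertices", (3,))
        tri = np.asarray(self.triangles)
        if tri.ndim != 2 or tri.shape[1] != 3:
            raise ValidationError(f"triangles: expected shape (n, 3), got {tri.shape}")
        self.triangles = tri.astype(np.int64)
        if len(self.triangles) == 0:
            raise ValidationError("mesh has zero triangles")
        nv = len(self.vertices)
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= nv:
            raise ValidationError("triangle indices out of range")
        # degenerate: repeated index within a triangle
        t = self.triangles
        bad = (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
        if bad.any():
            raise ValidationError(f"degenerate triangle (repeated vertex) at ids {np.flatnonzero(bad)[:10].tolist()}")
        areas = self.triangle_areas()
        zero = areas <= 0.0
        if zero.any():
            raise ValidationError(f"zero-area triangle at ids {np.flatnonzero(zero)[:10].tolist()}")
        if self.vertex_normals is not None:
            self.vertex_normals = _as_float_array(self.vertex_normals, "vertex_normals", (3,))
            if len(self.vertex_normals) != nv:
                raise ValidationError("vertex_normals length mismatch")

    # -- derived geometry ------------------------------------------------
    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        t = self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def triangle_areas(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def triangle_normals(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def triangle_centroids(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return (a + b + c) / 3.0

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def edges(self, unique: bool = True) -> np.ndarray:
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0) if unique else e

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.triangles, process=False)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            None if self.vertex_normals is None else self.vertex_normals.copy(),
        )


@dataclass
class Centerline:
    """Ordered arc-length-parameterised polyline: the vessel skeleton."""

    points: np.ndarray
    arc_length: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.points = _as_float_array(self.points, "centerline points", (3,))
        if len(self.points) < 3:
            raise ValidationError("centerline needs at least 3 points")
        if self.arc_length is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self.arc_length = np.asarray(self.arc_length, dtype=float)
        if self.arc_length.shape != (len(self.points),):
            raise ValidationError("arc_length length mismatch")
        if self.arc_length[0] != 0.0 or (np.diff(self.arc_length) <= 0).any():
            raise ValidationError("arc_length must start at 0 and be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s) -> np.ndarray:
        """Linear interpolation of position at arc length(s) ``s``."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        out = np.empty(np.shape(s) + (3,))
        for k in range(3):
            out[..., k] = np.interp(s, self.arc_length, self.points[:, k])
        return out

    def tangent_at(self, s) -> np.ndarray:
        """Unit tangent at arc length ``s`` (central differences on segments)."""
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        eps = max(self.length * 1e-6, 1e-12)
        lo = np.clip(s_arr - eps, 0.0, self.length)
        hi = np.clip(s_arr + eps, 0.0, self.length)
        d = self.point_at(hi) - self.point_at(lo)
        d /= np.linalg.norm(d, axis=-1, keepdims=True)
        return d[0] if np.isscalar(s) or np.ndim(s) == 0 else d


@dataclass
class Plane:
    """Oriented plane given by a point and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValidationError("plane normal must be nonzero")
            self.normal = self.normal / n

    def signed_distance(self, points) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic orthonormal in-plane basis (u, v) with u x v = normal."""
        n = self.normal
        ref = np.array([1.0, 0.0, 0.0])
        if abs(n @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = ref - (ref @ n) * n
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v


@dataclass
class CrossSection:
    """Planar cut of the vessel wall with its enclosed area."""

    plane: Plane
    equivalent_diameter: float
    section_area: float

    def __post_init__(self):
        if self.section_area <= 0 or self.equivalent_diameter <= 0:
            raise ValidationError("cross-section area and diameter must be positive")
        expected = 2.0 * np.sqrt(self.section_area / np.pi)
        if abs(self.equivalent_diameter - expected) > 1e-9 * max(1.0, expected):
            raise ValidationError("equivalent_diameter inconsistent with section_area")


@dataclass
class WssSeries:
    """Per-vertex wall-shear-stress vectors at uniform instants over one cycle.

    times : (nt,) uniformly spaced in [0, T); the cycle period is T
    tau : (nt, nv, 3) Pa
    """

    mesh: SurfaceMesh
    times: np.ndarray
    tau: np.ndarray
    period: float = None  # type: ignore[assignment]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        nt = len(self.times)
        if nt < 2:
            raise ValidationError("WSS series needs at least 2 time steps")
        if self.tau.shape != (nt, len(self.mesh.vertices), 3):
            raise ValidationError(
                f"tau shape {self.tau.shape} does not match ({nt}, {len(self.mesh.vertices)}, 3)"
            )
        if not np.isfinite(self.tau).all():
            raise ValidationError("non-finite WSS values")
        dt = np.diff(self.times)
        if self.period is None:
            self.period = float(self.times[-1] + dt.mean())
        if (dt <= 0).any() or np.abs(dt - dt.mean()).max() > 1e-9 * self.period:
            raise ValidationError("time samples must be uniformly spaced")
        if self.times[0] != 0.0:
            self.times = self.times - self.times[0]

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return self.period / self.n_times


@dataclass
class VolumeField:
    """Tetrahedral volume mesh with a per-point velocity field (m/s)."""

    points: np.ndarray
    tets: np.ndarray
    velocity: np.ndarray

    def __post_init__(self):
        self.points = _as_float_array(self.points, "points", (3,))
        tets = np.asarray(self.tets)
        if tets.ndim != 2 or tets.shape[1] != 4:
            raise ValidationError(f"tets: expected (n, 4), got {tets.shape}")
        self.tets = tets.astype(np.int64)
        self.velocity = _as_float_array(self.velocity, "velocity", (3,))
        if len(self.velocity) != len(self.points):
            raise ValidationError("velocity length must match points")
        vols = self.tet_volumes(signed=True)
        if (np.abs(vols) <= 0).any():
            raise ValidationError(f"degenerate tet at ids {np.flatnonzero(np.abs(vols) <= 0)[:10].tolist()}")
        # orient consistently: flip tets with negative signed volume
        neg = vols < 0
        if neg.any():
            self.tets[neg] = self.tets[neg][:, [0, 2, 1, 3]]

    def tet_volumes(self, signed: bool = False) -> np.ndarray:
        p = self.points
        t = self.tets
        a = p[t[:, 1]] - p[t[:, 0]]
        b = p[t[:, 2]] - p[t[:, 0]]
        c = p[t[:, 3]] - p[t[:, 0]]
        v = np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0
        return v if signed else np.abs(v)

    def tet_centroids(self) -> np.ndarray:
        return self.points[self.tets].mean(axis=1)


@dataclass
class RoiPatch:
    """A subset of mesh triangles marking an aneurysm-inception region."""

    mesh: SurfaceMesh
    triangle_ids: np.ndarray
    area: float = None  # type: ignore[assignment]

    def __post_init__(self):
        ids = np.asarray(self.triangle_ids, dtype=np.int64)
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("duplicate triangle ids in ROI")
        if len(ids) and (ids.min() < 0 or ids.max() >= len(self.mesh.triangles)):
            raise ValidationError("ROI triangle ids out of range")
        self.triangle_ids = ids
        true_area = float(self.mesh.triangle_areas()[ids].sum()) if len(ids) else 0.0
        if self.area is None:
            self.area = true_area
        elif abs(self.area - true_area) > 1e-9 * max(true_area, 1.0):
            raise ValidationError("ROI area inconsistent with listed triangles")

    def __len__(self) -> int:
        return len(self.triangle_ids)

    def centroids(self) -> np.ndarray:
        return self.mesh.triangle_centroids()[self.triangle_ids]

    def vertices_ids(self) -> np.ndarray:
        return np.unique(self.mesh.triangles[self.triangle_ids])


@dataclass
class Config:
    """Run-wide physical constants and algorithm defaults.

    Blood is treated as incompressible and Newtonian with rigid no-slip
    walls; the viscosity/density defaults are the standard values for
    cerebral CFD.  ``vortex_threshold_fraction`` is the fraction of the
    positive peak Q used to binarise vortex cores at peak systole.
    """

    blood_viscosity: float = 0.0035  # Pa·s
    blood_density: float = 1066.0  # kg/m³
    time_points_per_cycle: int = 100
    winding_tolerance_deg: float = 1.0
    vortex_threshold_fraction: float = 0.08
    length_unit_scale: float = 1e-3  # geometry unit -> metres (mm default)
    random_seed: int = 20221109

    def __post_init__(self):
        for name in (
            "blood_viscosity",
            "blood_density",
            "time_points_per_cycle",
            "winding_tolerance_deg",
            "vortex_threshold_fraction",
            "length_unit_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"Config.{name} must be positive")
        if not (0.0 < self.vortex_threshold_fraction < 1.0):
            raise ValidationError("vortex_threshold_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "blood_viscosity": self.blood_viscosity,
            "blood_density": self.blood_density,
            "time_points_per_cycle": self.time_points_per_cycle,
            "winding_tolerance_deg": self.winding_tolerance_deg,
            "vortex_threshold_fraction": self.vortex_threshold_fraction,
            "length_unit_scale": self.length_unit_scale,
            "random_seed": self.random_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
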