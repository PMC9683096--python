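"""Synthetic vessel phantoms, analytic WSS series and velocity fields.

Clinical tandem-aneurysm datasets (CTA segmentations, CFD fields) are not
distributable, so every downstream stage is exercised on phantoms: a tube
swept along a known centerline carrying one or two saccular bulges, with
ground-truth neck annotations and inception regions recorded at build
time.  WSS and velocity fields are analytic, chosen so the surface
indicators and the Q-criterion have closed-form values.

The bulge is a compactly supported C-infinity bump

    f(q) = exp(k (1 - 1/(1 - q^2))),  q < 1,  k = 0.5,

applied as an outward radial displacement, where q is an elliptic
coordinate in (arc length, circumferential arc) scaled by the bulge
width.  Compact support keeps the displacement exactly zero outside the
bulge, so the ground-truth inception footprint (displaced triangles) and
the 5%-amplitude neck curve are nested level sets close to each other —
the geometric situation the region-of-interest criterion is meant to
resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import rotation_minimizing_frames
from .types import Centerline, Plane, RoiPatch, SurfaceMesh, ValidationError, VolumeField, WssSeries

__all__ = [
    "Bulge",
    "PhantomSpec",
    "BulgeAnnotation",
    "PhantomBundle",
    "make_phantom",
    "analytic_wss_series",
    "analytic_velocity",
    "cardiac_waveform",
    "box_tet_mesh",
    "cylinder_tet_mesh",
]

BUMP_SHARPNESS = 0.5
NECK_LEVEL = 0.05  # neck curve = level set at this fraction of bulge amplitude
NECK_POINTS = 64
GT_DISPLACEMENT_FACTOR = 1e-6  # of tube radius


def bump(q: np.ndarray, k: float = BUMP_SHARPNESS) -> np.ndarray:
    """Compact C-infinity bump: 1 at q=0, exactly 0 for q >= 1."""
    q = np.asarray(q, dtype=float)
    out = np.zeros_like(q)
    inside = np.abs(q) < 1.0
    qi = q[inside]
    out[inside] = np.exp(k * (1.0 - 1.0 / (1.0 - qi * qi)))
    return out


def bump_inverse(level: float, k: float = BUMP_SHARPNESS) -> float:
    """q such that bump(q) = level (0 < level < 1)."""
    return float(np.sqrt(1.0 - 1.0 / (1.0 - np.log(level) / k)))


@dataclass
class Bulge:
    """One saccular bulge: centre arc length, amplitude, width (mm), and
    the outward direction on the wall it grows from."""

    s_center: float
    amplitude: float
    width: float
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValidationError("bulge direction must be nonzero")
        self.direction = self.direction / n
        if self.amplitude <= 0 or self.width <= 0:
            raise ValidationError("bulge amplitude and width must be positive")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic vessel phantom."""

    centerline_kind: str = "arc"  # line | arc | spline
    length: float = 40.0  # mm
    radius: float = 2.0  # mm (inlet)
    radius_out: float | None = None  # linear taper when given
    bulges: list[Bulge] = field(default_factory=list)
    circumferential_resolution: int = 48  # m
    axial_resolution: int = 120  # n
    arc_radius: float | None = None  # curvature radius for kind="arc"
    seed: int = 20221109

    def __post_init__(self):
        if self.radius <= 0 or (self.radius_out is not None and self.radius_out <= 0):
            raise ValidationError("radii must be positive")
        if self.circumferential_resolution < 8 or self.axial_resolution < 10:
            raise ValidationError("need m >= 8 and n >= 10")
        if self.centerline_kind not in ("line", "arc", "spline"):
            raise ValidationError(f"unknown centerline kind {self.centerline_kind!r}")
        for b in self.bulges:
            if not (0.0 < b.s_center < self.length):
                raise ValidationError("bulge centre must lie strictly inside the tube")

    def radius_at(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.radius_out is None:
            return np.full_like(s, self.radius)
        return self.radius + (self.radius_out - self.radius) * s / self.length


@dataclass
class BulgeAnnotation:
    """Ground truth recorded for one bulge at phantom-build time."""

    neck_plane: Plane
    neck_curve: np.ndarray  # (k, 3), closed (first point repeated last)
    roi: RoiPatch  # on the clean mesh (same triangulation as diseased)
    bulge: Bulge


@dataclass
class PhantomBundle:
    diseased_mesh: SurfaceMesh
    clean_mesh: SurfaceMesh
    centerline: Centerline
    annotations: list[BulgeAnnotation]
    spec: PhantomSpec


# ------------------------------------------------------------- centerlines
def _centerline_points(spec: PhantomSpec, n_points: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_points)
    L = spec.length
    if spec.centerline_kind == "line":
        return np.column_stack([L * t, np.zeros(n_points), np.zeros(n_points)])
    if spec.centerline_kind == "arc":
        Rc = spec.arc_radius if spec.arc_radius is not None else L
        phi = L / Rc  # subtended angle
        ang = phi * t
        # arc in the xy-plane starting at the origin heading along +x
        return np.column_stack([Rc * np.sin(ang), Rc * (1.0 - np.cos(ang)), np.zeros(n_points)])
    # spline: smooth pseudo-random undulation, deterministic in the seed
    rng = np.random.default_rng(spec.seed)
    phase = rng.uniform(0, 2 * np.pi, size=4)
    y = 0.06 * L * np.sin(2 * np.pi * t + phase[0]) + 0.03 * L * np.sin(4 * np.pi * t + phase[1])
    z = 0.04 * L * np.sin(2 * np.pi * t + phase[2]) + 0.02 * L * np.sin(6 * np.pi * t + phase[3])
    return np.column_stack([L * t, y, z])


# ------------------------------------------------------------------ phantom
def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build the diseased (bulged) and clean tube pair with ground truth.

    Both meshes share one triangulation: the diseased mesh is the clean
    tube displaced radially outward by the bump of each bulge, so they
    are identical (bitwise) outside the bulge supports.
    """
    # bulges must be separated along arc length (tandem, not overlapping)
    intervals = sorted((b.s_center - b.width, b.s_center + b.width) for b in spec.bulges)
    for (a0, a1), (b0, _) in zip(intervals, intervals[1:]):
        if b0 < a1:
            raise ValidationError("bulge supports overlap; tandem bulges must be separated")

    n, m = spec.axial_resolution, spec.circumferential_resolution
    s = np.linspace(0.0, spec.length, n)
    cl_pts = _centerline_points(spec, max(4 * n, 200))
    centerline = Centerline(cl_pts)
    # arc length of the discrete centerline may differ slightly from the
    # nominal length; rescale station positions onto it
    s_stations = s * (centerline.length / spec.length)
    station_pts = centerline.point_at(s_stations)
    tangents = centerline.tangent_at(s_stations)
    _, u, v = rotation_minimizing_frames(station_pts, tangents)

    radii = spec.radius_at(s)
    phi = 2 * np.pi * np.arange(m) / m  # ring azimuths
    cosphi, sinphi = np.cos(phi), np.sin(phi)

    # radial unit vectors, (n, m, 3)
    radial = cosphi[None, :, None] * u[:, None, :] + sinphi[None, :, None] * v[:, None, :]
    clean_pts = station_pts[:, None, :] + radii[:, None, None] * radial

    # displacement per bulge, (n_bulges, n, m)
    disp = np.zeros((len(spec.bulges), n, m))
    for ib, b in enumerate(spec.bulges):
        phi_b = np.arctan2(v @ b.direction, u @ b.direction)  # bulge azimuth per station
        dphi = _wrap_angle(phi[None, :] - phi_b[:, None])
        ds = s[:, None] - b.s_center
        q = np.sqrt(ds**2 + (radii[:, None] * dphi) ** 2) / b.width
        disp[ib] = b.amplitude * bump(q)
    total_disp = disp.sum(axis=0)
    diseased_pts = clean_pts + total_disp[..., None] * radial

    triangles = _tube_triangles(n, m)
    clean_v, diseased_v, tri, cap_info = _cap_tube(clean_pts, diseased_pts, station_pts, triangles, n, m)
    clean = SurfaceMesh(clean_v, tri)
    diseased = SurfaceMesh(diseased_v, tri.copy())
    _orient_outward(clean)
    _orient_outward(diseased)

    vertex_disp = np.zeros((len(spec.bulges), len(clean_v)))
    vertex_disp[:, : n * m] = disp.reshape(len(spec.bulges), n * m)

    annotations = []
    for ib, b in enumerate(spec.bulges):
        gt_tri = np.flatnonzero(vertex_disp[ib][clean.triangles].max(axis=1) > GT_DISPLACEMENT_FACTOR * spec.radius)
        roi = RoiPatch(clean, gt_tri)
        neck_plane, neck_curve = _neck_annotation(spec, centerline, b)
        annotations.append(BulgeAnnotation(neck_plane, neck_curve, roi, b))

    return PhantomBundle(diseased, clean, centerline, annotations, spec)


def _tube_triangles(n: int, m: int) -> np.ndarray:
    i = np.arange(n - 1)[:, None]
    j = np.arange(m)[None, :]
    j1 = (j + 1) % m
    a = i * m + j
    b = i * m + j1
    c = (i + 1) * m + j1
    d = (i + 1) * m + j
    quads = np.stack([a, b, c, d], axis=-1).reshape(-1, 4)
    return np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])


def _cap_tube(clean_pts, diseased_pts, station_pts, triangles, n, m):
    """Append end-cap fan vertices/triangles; returns flat vertex arrays."""
    clean_v = clean_pts.reshape(-1, 3)
    diseased_v = diseased_pts.reshape(-1, 3)
    centers = np.array([station_pts[0], station_pts[-1]])
    clean_v = np.vstack([clean_v, centers])
    diseased_v = np.vstack([diseased_v, centers])
    c0, c1 = n * m, n * m + 1
    j = np.arange(m)
    j1 = (j + 1) % m
    cap0 = np.column_stack([np.full(m, c0), j1, j])  # inlet ring, reversed winding
    last = (n - 1) * m
    cap1 = np.column_stack([np.full(m, c1), last + j, last + j1])
    tri = np.concatenate([triangles, cap0, cap1])
    return clean_v, diseased_v, tri, (c0, c1)


def _orient_outward(mesh: SurfaceMesh) -> None:
    """Flip all triangles if the signed volume is negative (inward normals)."""
    a, b, c = mesh.triangle_corners()
    vol = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    if vol < 0:
        mesh.triangles[:] = mesh.triangles[:, [0, 2, 1]]


def _neck_annotation(spec: PhantomSpec, centerline: Centerline, b: Bulge):
    """Neck plane (tangent plane at the bulge apex root) and neck curve
    (the level set where displacement = NECK_LEVEL * amplitude) on the
    diseased surface, resampled to NECK_POINTS points and closed."""
    scale = centerline.length / spec.length
    q_neck = bump_inverse(NECK_LEVEL)
    psi = 2 * np.pi * np.arange(NECK_POINTS) / NECK_POINTS
    ds = q_neck * b.width * np.cos(psi)
    arc = q_neck * b.width * np.sin(psi)

    s_pts = b.s_center + ds
    station = centerline.point_at(s_pts * scale)
    tang = centerline.tangent_at(s_pts * scale)
    _, u, v = rotation_minimizing_frames(station, tang)
    r_s = spec.radius_at(s_pts)
    phi_b = np.arctan2(np.einsum("ij,j->i", v, b.direction), np.einsum("ij,j->i", u, b.direction))
    phi = phi_b + arc / r_s
    radial = np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v
    curve = station + (r_s + NECK_LEVEL * b.amplitude)[:, None] * radial
    curve = np.vstack([curve, curve[:1]])  # close

    s0 = b.s_center * scale
    p0 = centerline.point_at(s0)
    t0 = centerline.tangent_at(s0)
    _, u0, v0 = rotation_minimizing_frames(np.vstack([p0, p0 + t0 * 1e-3]), np.vstack([t0, t0]))
    d0 = b.direction - (b.direction @ t0) * t0
    d0 /= np.linalg.norm(d0)
    origin = p0 + float(spec.radius_at(b.s_center)) * d0
    return Plane(origin, d0), curve


# ----------------------------------------------------------- WSS generators
def _spatial_scale(mesh: SurfaceMesh, params: dict) -> np.ndarray:
    """Optional spatial modulation of the WSS magnitude.

    params["gradient"]: 3-vector g -> scale 1 + g.(x - centroid)
    params["hotspots"]: list of (center, amplitude, width) Gaussian factors
    """
    scale = np.ones(len(mesh.vertices))
    if "gradient" in params:
        g = np.asarray(params["gradient"], dtype=float)
        scale = scale + (mesh.vertices - mesh.vertices.mean(axis=0)) @ g
    for center, amp, width in params.get("hotspots", []):
        d2 = ((mesh.vertices - np.asarray(center, float)) ** 2).sum(axis=1)
        scale = scale * (1.0 + amp * np.exp(-d2 / (2.0 * width**2)))
    return scale


def analytic_wss_series(kind: str, params: dict, mesh: SurfaceMesh, n_times: int = 100, period: float = 0.8) -> WssSeries:
    """WSS series with closed-form time structure on an arbitrary surface.

    kinds
    -----
    steady              tau(t) = tau0
    pulsating_magnitude tau(t) = tau0 (1 + a sin(2 pi t / T)),  |a| < 1
    reversing           tau(t) = tau0 (bias + sin(2 pi t / T)), bias in [0, 1);
                        the direction flips sign over part of the cycle.  With
                        bias = 0 (default) the cycle-mean vector is exactly
                        zero, which makes the AFI angle undefined; use a small
                        positive bias to exercise AFI on a reversing field.
    rotating            |tau| constant, direction spinning in the local
                        tangent plane at one revolution per cycle
    """
    if n_times < 2:
        raise ValidationError("need at least 2 time steps")
    times = period * np.arange(n_times) / n_times
    omega_t = 2 * np.pi * times / period
    nv = len(mesh.vertices)
    tau0 = np.asarray(params.get("tau0", [1.0, 0.0, 0.0]), dtype=float)
    base = np.broadcast_to(tau0, (nv, 3)).copy() if tau0.ndim == 1 else tau0
    base = base * _spatial_scale(mesh, params)[:, None]

    if kind == "steady":
        tau = np.broadcast_to(base, (n_times, nv, 3)).copy()
    elif kind == "pulsating_magnitude":
        a = float(params.get("a", 0.5))
        if abs(a) >= 1.0:
            raise ValidationError("pulsating_magnitude needs |a| < 1 (magnitude must stay positive)")
        tau = (1.0 + a * np.sin(omega_t))[:, None, None] * base[None]
    elif kind == "reversing":
        bias = float(params.get("bias", 0.0))
        if not (0.0 <= bias < 1.0):
            raise ValidationError("reversing bias must be in [0, 1) so the direction still flips")
        tau = (bias + np.sin(omega_t))[:, None, None] * base[None]
    elif kind == "rotating":
        from .hemodynamics import tangent_frames

        fr = tangent_frames(mesh)
        mag = np.linalg.norm(base, axis=1)
        tau = (
            np.cos(omega_t)[:, None, None] * (mag[:, None] * fr.p)[None]
            + np.sin(omega_t)[:, None, None] * (mag[:, None] * fr.q)[None]
        )
    else:
        raise ValidationError(f"unknown WSS series kind {kind!r}")
    return WssSeries(mesh, times, tau, period=period)


# ------------------------------------------------------- velocity generators
def evaluate_velocity(kind: str, params: dict, points: np.ndarray) -> np.ndarray:
    """Closed-form velocity fields with known velocity-gradient structure."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    u = np.zeros_like(p)
    if kind == "solid_rotation":
        w = float(params.get("omega", 1.0))
        u[:, 0], u[:, 1] = -w * y, w * x
    elif kind == "pure_shear":
        g = float(params.get("gamma", 1.0))
        u[:, 0] = g * y
    elif kind == "planar_strain":
        g = float(params.get("gamma", 1.0))
        u[:, 0], u[:, 1] = g * x, -g * y
    elif kind == "poiseuille":
        U = float(params.get("u_max", 1.0))
        R = float(params.get("radius", 1.0))
        r2 = x**2 + y**2
        uz = U * (1.0 - r2 / R**2)
        outside = uz < 0
        if outside.any():
            from .io import log

            log.warning("poiseuille evaluated outside the tube at %d points; clamped to 0", int(outside.sum()))
            uz = np.where(outside, 0.0, uz)
        u[:, 2] = uz
    elif kind == "lamb_oseen":
        G = float(params.get("circulation", 1.0))
        rc = float(params.get("core_radius", 0.3))
        r2 = x**2 + y**2
        r = np.sqrt(r2)
        with np.errstate(divide="ignore", invalid="ignore"):
            utheta = G / (2 * np.pi * r) * (1.0 - np.exp(-r2 / rc**2))
        utheta = np.where(r < 1e-12, 0.0, utheta)
        u[:, 0] = -utheta * np.where(r < 1e-12, 0.0, y / np.maximum(r, 1e-300))
        u[:, 1] = utheta * np.where(r < 1e-12, 0.0, x / np.maximum(r, 1e-300))
    else:
        raise ValidationError(f"unknown velocity kind {kind!r}")
    return u


def analytic_velocity(kind: str, params: dict, points: np.ndarray, tets: np.ndarray) -> VolumeField:
    return VolumeField(points, tets, evaluate_velocity(kind, params, points))


# ------------------------------------------------------------- tet meshing
# Kuhn (path) subdivision: all 6 tets share the main diagonal 0-6 and the
# induced face diagonals match across translated cubes, so face adjacency
# of the lattice is connected.
_CUBE_TETS = np.array(
    [[0, 1, 2, 6], [0, 1, 5, 6], [0, 3, 2, 6], [0, 3, 7, 6], [0, 4, 5, 6], [0, 4, 7, 6]]
)


def box_tet_mesh(lo, hi, shape) -> tuple[np.ndarray, np.ndarray]:
    """Structured box lattice split into 6 tets per cube (no degenerates)."""
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    nx, ny, nz = shape
    xs = [np.linspace(lo[k], hi[k], s + 1) for k, s in enumerate((nx, ny, nz))]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corners = np.stack(
        [
            vid(I, J, K), vid(I + 1, J, K), vid(I + 1, J + 1, K), vid(I, J + 1, K),
            vid(I, J, K + 1), vid(I + 1, J, K + 1), vid(I + 1, J + 1, K + 1), vid(I, J + 1, K + 1),
        ],
        axis=1,
    )
    tets = corners[:, _CUBE_TETS].reshape(-1, 4)
    return points, tets


def cylinder_tet_mesh(radius: float, length: float, n_radial: int = 10, n_axial: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Tet mesh filling a z-axis cylinder, carved from a box lattice."""
    n_xy = 2 * n_radial
    points, tets = box_tet_mesh(
        (-radius, -radius, 0.0), (radius, radius, length), (n_xy, n_xy, n_axial)
    )
    r2 = points[:, 0] ** 2 + points[:, 1] ** 2
    keep_pt = r2 <= radius**2 * (1.0 + 1e-12)
    keep_tet = keep_pt[tets].all(axis=1)
    tets = tets[keep_tet]
    used = np.zeros(len(points), dtype=bool)
    used[tets] = True
    remap = np.cumsum(used) - 1
    return points[used], remap[tets]


# ---------------------------------------------------------------- waveform
def cardiac_waveform(period: float = 0.8, n: int = 100):
    """Smooth positive single-peaked periodic pulse (von-Mises-shaped).

    Returns (times, values, peak_index).  The phantom pipeline uses this
    as a stand-in inflow waveform; it is not calibrated to physiology
    beyond being positive, periodic, and systole-peaked.
    """
    if period <= 0 or n < 2:
        raise ValidationError("need period > 0 and n >= 2")
    times = period * np.arange(n) / n
    phase = 2 * np.pi * (times / period - 0.15)
    values = 0.3 + 0.7 * np.exp(3.0 * (np.cos(phase) - 1.0))
    return times, values, int(np.argmax(values))
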