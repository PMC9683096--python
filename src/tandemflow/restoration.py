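"""Parent-vessel restoration: replace an aneurysmal segment with a tube.

The restoration removes the wall between two operator-placed cut planes
(chosen where the vessel diameter shows no mutation), measures the
inflow/outflow cross-sections, sweeps a tube of linearly varying
equivalent diameter along the skeleton between the cuts using
rotation-minimizing frames, and stitches the tube to the cut boundary
loops.  Applied to the proximal segment only, the distal segment only,
or both, this yields the Model P / Model D / Model A family of
hypothetical pre-aneurysm vasculatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from trimesh.intersections import slice_mesh_plane

from .frames import rotation_minimizing_frames
from .io import validate_mesh
from .types import Centerline, CrossSection, Plane, SurfaceMesh, ValidationError

__all__ = [
    "RestorationJob",
    "ModelVariants",
    "measure_cross_section",
    "clip_segment",
    "loft_tube",
    "restore",
    "build_model_variants",
]


@dataclass
class RestorationJob:
    """One restoration task: which arc-length segment of the skeleton to
    replace, and at what resolution."""

    mesh: SurfaceMesh
    centerline: Centerline
    s_in: float
    s_out: float
    circumferential_resolution: int = 64
    axial_stations: int | None = None  # default max(10, length/0.25mm)
    junction_smoothing_steps: int = 5

    def __post_init__(self):
        if not (0.0 < self.s_in < self.s_out < self.centerline.length):
            raise ValidationError("need 0 < s_in < s_out < centerline length")

    def n_stations(self) -> int:
        if self.axial_stations is not None:
            return max(2, self.axial_stations)
        return max(10, int(round((self.s_out - self.s_in) / 0.25)))

    def cut_planes(self) -> tuple[Plane, Plane]:
        """Cut planes normal to the centerline tangent at s_in / s_out."""
        return (
            Plane(self.centerline.point_at(self.s_in), self.centerline.tangent_at(self.s_in)),
            Plane(self.centerline.point_at(self.s_out), self.centerline.tangent_at(self.s_out)),
        )


@dataclass
class ModelVariants:
    model_P: SurfaceMesh
    model_D: SurfaceMesh
    model_A: SurfaceMesh
    provenance: dict


# ------------------------------------------------------------ cross-section
def measure_cross_section(mesh: SurfaceMesh, plane: Plane) -> CrossSection:
    """Intersect the wall with a plane and return the enclosed area of the
    intersection loop nearest the plane origin."""
    tm = mesh.as_trimesh()
    section = tm.section(plane_origin=plane.origin, plane_normal=plane.normal)
    if section is None:
        raise ValidationError("plane does not intersect the mesh")
    loops = section.discrete
    if not loops:
        raise ValidationError("plane does not intersect the mesh")
    best_area = None
    best_dist = np.inf
    for loop in loops:
        loop = np.asarray(loop)
        if not np.allclose(loop[0], loop[-1], atol=1e-7 * max(1.0, np.abs(loop).max())):
            raise ValidationError("open intersection curve: mesh is not locally watertight")
        dist = np.linalg.norm(loop.mean(axis=0) - plane.origin)
        if dist < best_dist:
            best_dist = dist
            best_area = _planar_polygon_area(loop[:-1], plane)
    area = abs(best_area)
    if area <= 0:
        raise ValidationError("degenerate intersection loop")
    return CrossSection(plane, equivalent_diameter=2.0 * np.sqrt(area / np.pi), section_area=area)


def _planar_polygon_area(pts3d: np.ndarray, plane: Plane) -> float:
    u, v = plane.basis()
    rel = pts3d - plane.origin
    x, y = rel @ u, rel @ v
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ----------------------------------------------------------------- clipping
def _slice_keep(mesh: SurfaceMesh, origin, normal) -> SurfaceMesh:
    """Keep the part of the mesh on the positive side of (origin, normal)."""
    tm = mesh.as_trimesh()
    cut = slice_mesh_plane(tm, plane_normal=np.asarray(normal, float), plane_origin=np.asarray(origin, float))
    if cut is None or len(cut.faces) == 0:
        raise ValidationError("clip removed the entire mesh")
    cut.merge_vertices()
    good = trimesh.triangles.nondegenerate(cut.triangles, height=1e-10)
    cut.update_faces(good)
    cut.remove_unreferenced_vertices()
    return SurfaceMesh(np.asarray(cut.vertices, float), np.asarray(cut.faces))


def _boundary_loops(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Ordered vertex-index loops of the mesh boundary (directed walk).

    Assumes consistent triangle winding; each loop starts at its
    lexicographically smallest vertex for determinism.
    """
    t = mesh.triangles
    directed = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = directed[counts[inverse] == 1]
    succ = {int(a): int(b) for a, b in boundary}
    loops = []
    seen = set()
    for start in succ:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = succ[start]
        while cur != start:
            if cur in seen or cur not in succ:
                raise ValidationError("non-manifold or branching boundary; cannot walk loops")
            loop.append(cur)
            seen.add(cur)
            cur = succ[cur]
        loop = np.array(loop, dtype=np.int64)
        k = int(np.lexsort(mesh.vertices[loop].T[::-1])[0])
        loops.append(np.roll(loop, -k))
    return loops


def _loops_in_plane(mesh: SurfaceMesh, plane: Plane, scale: float) -> list[np.ndarray]:
    out = []
    for loop in _boundary_loops(mesh):
        d = np.abs(plane.signed_distance(mesh.vertices[loop]))
        if d.max() < 1e-6 * scale:
            out.append(loop)
    return out


def clip_segment(mesh: SurfaceMesh, plane_in: Plane, plane_out: Plane) -> dict:
    """Remove the wall strictly between the two cut planes.

    The plane normals must both point downstream (from in to out).
    Returns the two retained parts, the merged open mesh, and the two
    boundary loops (as ordered point arrays lying in the cut planes).
    """
    gap = plane_in.signed_distance(plane_out.origin[None])[0]
    if gap <= 0:
        raise ValidationError("cut planes out of order (s_out must be downstream of s_in)")
    scale = float(np.linalg.norm(mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)))
    proximal = _slice_keep(mesh, plane_in.origin, -plane_in.normal)
    distal = _slice_keep(mesh, plane_out.origin, plane_out.normal)
    loops_in = _loops_in_plane(proximal, plane_in, scale)
    loops_out = _loops_in_plane(distal, plane_out, scale)
    if len(loops_in) != 1 or len(loops_out) != 1:
        raise ValidationError(
            f"each cut must produce exactly one loop (got {len(loops_in)} proximal, {len(loops_out)} distal)"
        )
    open_mesh = SurfaceMesh(
        np.vstack([proximal.vertices, distal.vertices]),
        np.vstack([proximal.triangles, distal.triangles + len(proximal.vertices)]),
    )
    return {
        "open_mesh": open_mesh,
        "proximal": proximal,
        "distal": distal,
        "loop_in": proximal.vertices[loops_in[0]],
        "loop_out": distal.vertices[loops_out[0]],
        "loop_in_ids": loops_in[0],
        "loop_out_ids": loops_out[0],
    }


# ------------------------------------------------------------------ lofting
def loft_tube(
    centerline: Centerline,
    s_in: float,
    s_out: float,
    d_in: float,
    d_out: float,
    m: int = 64,
    n: int = 40,
    end_inset: float = 0.0,
) -> SurfaceMesh:
    """Open tube swept along the skeleton, diameter linear in arc length.

    Rings of ``m`` points sit in the plane normal to the local tangent,
    oriented by rotation-minimizing frames.  ``end_inset`` shifts the
    first/last station off the cut planes (used by the stitcher so ring
    and cut-loop vertices can never coincide).  Raises when the local
    curvature radius drops below the tube radius (self-intersection).
    """
    if d_in <= 0 or d_out <= 0:
        raise ValidationError("diameters must be positive")
    if n < 2:
        raise ValidationError("need at least 2 stations")
    s = np.linspace(s_in + end_inset, s_out - end_inset, n)
    radii = 0.5 * (d_in + (d_out - d_in) * (s - s_in) / (s_out - s_in))
    pts = centerline.point_at(s)
    tang = centerline.tangent_at(s)
    t, u, v = rotation_minimizing_frames(pts, tang)

    ds = np.gradient(s)
    kappa = np.linalg.norm(np.gradient(t, axis=0) / ds[:, None], axis=1)
    bad = kappa * radii > 1.0
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"centerline curvature radius {1 / kappa[k]:.3g} below tube radius {radii[k]:.3g} at station {k}"
        )

    phi = 2 * np.pi * np.arange(m) / m
    ring = np.cos(phi)[None, :, None] * u[:, None, :] + np.sin(phi)[None, :, None] * v[:, None, :]
    verts = (pts[:, None, :] + radii[:, None, None] * ring).reshape(-1, 3)

    i = np.arange(n - 1)[:, None]
    j = np.arange(m)[None, :]
    j1 = (j + 1) % m
    a = i * m + j
    b = i * m + j1
    c = (i + 1) * m + j1
    d = (i + 1) * m + j
    tri = np.concatenate(
        [np.stack([a, b, c], axis=-1).reshape(-1, 3), np.stack([a, c, d], axis=-1).reshape(-1, 3)]
    )
    mesh = SurfaceMesh(verts, tri)
    # orient outward (normals away from the centerline)
    mid = mesh.triangle_centroids() - centerline.point_at((s_in + s_out) / 2.0)
    if np.einsum("ij,ij->i", mesh.triangle_normals(), mid).mean() < 0:
        mesh.triangles[:] = mesh.triangles[:, [0, 2, 1]]
    return mesh


# ----------------------------------------------------------------- stitching
def _orient_loop(points: np.ndarray, plane: Plane) -> np.ndarray:
    """Indices reordering the loop counter-clockwise about the plane normal."""
    area = _planar_polygon_area(points, plane)
    return np.arange(len(points)) if area >= 0 else np.arange(len(points))[::-1]


def _zip_loops(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Greedy triangulated band between two closed polylines.

    Returns (k, 3) index triples where indices < len(pa) refer to loop A
    and the rest to loop B (offset by len(pa)).
    """
    na, nb = len(pa), len(pb)
    start_b = int(np.argmin(np.linalg.norm(pb - pa[0], axis=1)))
    tris = []
    ia = ib = 0
    while ia < na or ib < nb:
        a0 = pa[ia % na]
        b0 = pb[(start_b + ib) % nb]
        adv_a = np.linalg.norm(pa[(ia + 1) % na] - b0) if ia < na else np.inf
        adv_b = np.linalg.norm(pb[(start_b + ib + 1) % nb] - a0) if ib < nb else np.inf
        if adv_a <= adv_b:
            tris.append([ia % na, (ia + 1) % na, na + (start_b + ib) % nb])
            ia += 1
        else:
            tris.append([ia % na, na + (start_b + ib + 1) % nb, na + (start_b + ib) % nb])
            ib += 1
    return np.array(tris, dtype=np.int64)


def _taubin_smooth(vertices: np.ndarray, edges: np.ndarray, movable: np.ndarray, steps: int) -> np.ndarray:
    """Volume-preserving (Taubin lambda/mu) smoothing of selected vertices."""
    if steps <= 0 or not movable.any():
        return vertices
    v = vertices.copy()
    nv = len(v)
    neighbors_sum = np.zeros_like(v)
    deg = np.zeros(nv)
    for lam in [0.5, -0.53] * steps:
        neighbors_sum[:] = 0.0
        deg[:] = 0.0
        np.add.at(neighbors_sum, edges[:, 0], v[edges[:, 1]])
        np.add.at(neighbors_sum, edges[:, 1], v[edges[:, 0]])
        np.add.at(deg, edges[:, 0], 1.0)
        np.add.at(deg, edges[:, 1], 1.0)
        lap = neighbors_sum / np.maximum(deg, 1.0)[:, None] - v
        v[movable] += lam * lap[movable]
    return v


def restore(job: RestorationJob) -> SurfaceMesh:
    """Run the full restoration on one segment and return a closed mesh."""
    report = validate_mesh(job.mesh)
    if not report["watertight"]:
        raise ValidationError(f"input mesh is not watertight ({report['boundary_edges']} boundary edges)")
    plane_in, plane_out = job.cut_planes()
    cs_in = measure_cross_section(job.mesh, plane_in)
    cs_out = measure_cross_section(job.mesh, plane_out)
    parts = clip_segment(job.mesh, plane_in, plane_out)

    n = job.n_stations()
    inset = 1e-4 * (job.s_out - job.s_in)
    tube = loft_tube(
        job.centerline,
        job.s_in,
        job.s_out,
        cs_in.equivalent_diameter,
        cs_out.equivalent_diameter,
        m=job.circumferential_resolution,
        n=n,
        end_inset=inset,
    )
    m = job.circumferential_resolution
    prox, dist = parts["proximal"], parts["distal"]
    off_d = len(prox.vertices)
    off_t = off_d + len(dist.vertices)
    vertices = np.vstack([prox.vertices, dist.vertices, tube.vertices])
    tris = [prox.triangles, dist.triangles + off_d, tube.triangles + off_t]

    ring_in = off_t + np.arange(m)
    ring_out = off_t + (n - 1) * m + np.arange(m)
    for loop_ids, part_off, ring, plane in (
        (parts["loop_in_ids"], 0, ring_in, plane_in),
        (parts["loop_out_ids"], off_d, ring_out, plane_out),
    ):
        loop_global = loop_ids + part_off
        order_l = _orient_loop(vertices[loop_global], plane)
        order_r = _orient_loop(vertices[ring], plane)
        la = loop_global[order_l]
        rb = ring[order_r]
        band = _zip_loops(vertices[la], vertices[rb])
        mapped = np.where(band < len(la), la[np.minimum(band, len(la) - 1)], rb[np.maximum(band - len(la), 0)])
        tris.append(mapped)

    mesh = SurfaceMesh(vertices, np.vstack(tris))
    tm = mesh.as_trimesh()
    trimesh.repair.fix_normals(tm)  # make winding globally consistent/outward
    mesh = SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))

    if job.junction_smoothing_steps > 0:
        movable = np.zeros(len(mesh.vertices), dtype=bool)
        seam = np.concatenate([ring_in, ring_out, parts["loop_in_ids"], parts["loop_out_ids"] + off_d])
        movable[seam] = True
        edges = mesh.edges()
        for _ in range(2):  # grow to a 2-ring band around the seams
            sel = movable[edges[:, 0]] | movable[edges[:, 1]]
            movable[edges[sel].ravel()] = True
        mesh = SurfaceMesh(_taubin_smooth(mesh.vertices, edges, movable, job.junction_smoothing_steps), mesh.triangles)

    final = validate_mesh(mesh)
    if not final["watertight"] or final["non_manifold_edges"]:
        raise ValidationError(
            f"stitching failed: {final['boundary_edges']} boundary edges, "
            f"{final['non_manifold_edges']} non-manifold edges"
        )
    return mesh


# ------------------------------------------------------------ model variants
def build_model_variants(
    mesh: SurfaceMesh,
    centerline: Centerline,
    proximal_segment: tuple[float, float],
    distal_segment: tuple[float, float],
    **job_kwargs,
) -> ModelVariants:
    """Model P (proximal restored), Model D (distal restored), Model A (both).

    The two segments must be disjoint in arc length; argument order does
    not matter (the upstream segment is taken as proximal).
    """
    segs = sorted([tuple(proximal_segment), tuple(distal_segment)])
    (p0, p1), (d0, d1) = segs
    if p1 > d0:
        raise ValidationError("segments overlap along arc length")

    def _restore(base: SurfaceMesh, seg: tuple[float, float]) -> SurfaceMesh:
        return restore(RestorationJob(base, centerline, seg[0], seg[1], **job_kwargs))

    model_P = _restore(mesh, (p0, p1))
    model_D = _restore(mesh, (d0, d1))
    model_A = _restore(model_P, (d0, d1))
    return ModelVariants(
        model_P=model_P,
        model_D=model_D,
        model_A=model_A,
        provenance={
            "proximal_segment": [p0, p1],
            "distal_segment": [d0, d1],
            "model_P": "proximal segment restored, distal kept intact",
            "model_D": "distal segment restored, proximal kept intact",
            "model_A": "both segments restored",
        },
    )
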