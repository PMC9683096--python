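"""Aneurysm-inception region (ROI) localisation on a restored vessel.

The aneurysm neck — an operator-selected plane plus a closed 3D curve
around the ostium — is the only annotation.  The restored wall is
projected orthogonally onto the neck plane; a wall point belongs to the
inception region when the neck curve winds a full 360 degrees around its
projection.  Because a tube has two walls that both project inside the
neck curve, candidates are restricted to a band near the plane on the
vessel side whose outward normal faces the neck (the far wall faces
away).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hemodynamics import tangent_frames
from .types import Plane, RoiPatch, SurfaceMesh, ValidationError

__all__ = ["NeckAnnotation", "project_to_plane", "winding_angle", "winding_angles", "extract_roi"]


@dataclass
class NeckAnnotation:
    """Neck plane + closed ordered neck curve (>= 8 points, first=last
    or implicitly cyclic; the curve need not be planar)."""

    plane: Plane
    curve: np.ndarray

    def __post_init__(self):
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.ndim != 2 or self.curve.shape[1] != 3:
            raise ValidationError("neck curve must be (k, 3)")
        # drop an explicit closing point; closure is cyclic from here on
        if np.allclose(self.curve[0], self.curve[-1]):
            self.curve = self.curve[:-1]
        if len(self.curve) < 8:
            raise ValidationError("neck curve needs at least 8 distinct points")

    def curve2d(self) -> np.ndarray:
        return project_to_plane(self.curve, self.plane)

    def diameter(self) -> float:
        c2 = self.curve2d()
        return float(2.0 * np.linalg.norm(c2 - c2.mean(axis=0), axis=1).max())


def project_to_plane(points, plane: Plane) -> np.ndarray:
    """Orthogonal projection along the plane normal, expressed in the
    plane's deterministic in-plane basis; returns (n, 2)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u, v = plane.basis()
    rel = pts - plane.origin
    return np.column_stack([rel @ u, rel @ v])


def winding_angles(points2d: np.ndarray, curve2d: np.ndarray) -> np.ndarray:
    """Total absolute winding angle (degrees) of the closed curve around
    each query point: 360 * |winding number| for points enclosed, ~0
    outside.  Vectorised over query points."""
    pts = np.atleast_2d(points2d)
    curve = np.asarray(curve2d, dtype=float)
    if len(curve) < 3:
        raise ValidationError("closed curve needs at least 3 points")
    a = curve[None, :, :] - pts[:, None, :]  # (np, nc, 2)
    b = np.roll(curve, -1, axis=0)[None, :, :] - pts[:, None, :]
    if (np.linalg.norm(a, axis=2) < 1e-12).any():
        raise ValidationError("query point coincides with a curve vertex")
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    dot = (a * b).sum(axis=2)
    total = np.degrees(np.arctan2(cross, dot).sum(axis=1))
    return np.abs(total)


def winding_angle(point2d, curve2d) -> float:
    return float(winding_angles(np.atleast_2d(point2d), curve2d)[0])


def extract_roi(
    mesh: SurfaceMesh,
    neck: NeckAnnotation,
    tolerance_deg: float = 1.0,
    band_factor: float = 2.0,
    triangle_rule: str = "all",
) -> RoiPatch:
    """Wall patch whose projection falls inside the neck curve.

    A vertex qualifies when (a) it lies within ``band_factor`` neck
    diameters of the plane on the vessel side, (b) its outward normal
    faces the neck plane (excludes the far wall), and (c) the neck curve
    winds >= 360 - tolerance_deg degrees around its projection.
    Triangles enter the patch when all three (``triangle_rule="all"``,
    conservative default) or any (``"any"``) vertices qualify.
    """
    curve2d = neck.curve2d()
    band = band_factor * neck.diameter()
    signed = neck.plane.signed_distance(mesh.vertices)
    # vessel side: beneath the neck plane (opposite the outward neck normal),
    # with a small allowance above for wall vertices straddling the plane
    near = (signed <= 0.05 * band) & (signed >= -band)
    normals = tangent_frames(mesh).n
    near &= normals @ neck.plane.normal > 0.0

    inside = np.zeros(len(mesh.vertices), dtype=bool)
    idx = np.flatnonzero(near)
    if len(idx):
        pts2d = project_to_plane(mesh.vertices[idx], neck.plane)
        ang = winding_angles(pts2d, curve2d)
        inside[idx] = ang >= 360.0 - tolerance_deg

    per_tri = inside[mesh.triangles]
    mask = per_tri.all(axis=1) if triangle_rule == "all" else per_tri.any(axis=1)
    tri_ids = np.flatnonzero(mask)
    if len(tri_ids) == 0:
        raise ValidationError(
            f"empty ROI (tolerance {tolerance_deg} deg, band {band:.3g}, "
            f"{len(idx)} candidate vertices, {int(inside.sum())} inside the neck curve)"
        )
    return RoiPatch(mesh, tri_ids)
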