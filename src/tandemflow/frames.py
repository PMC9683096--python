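"""Rotation-minimizing (parallel-transport) frames along a polyline.

Frenet frames flip at inflection points and spin near-straight segments,
which would twist any tube swept along the curve; the double-reflection
parallel transport used here keeps the frame continuous for arbitrary
smooth centerlines.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rotation_minimizing_frames"]


def rotation_minimizing_frames(points: np.ndarray, tangents: np.ndarray | None = None):
    """Return per-point orthonormal frames (t, u, v) with minimal twist.

    Implements the double-reflection method (Wang et al. 2008), which is
    second-order accurate in the sampling step.

    Parameters
    ----------
    points : (n, 3) polyline vertices
    tangents : optional (n, 3) unit tangents; estimated by central
        differences when omitted.

    Returns
    -------
    t, u, v : three (n, 3) arrays; ``u x v = t`` at every point.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if tangents is None:
        t = np.empty_like(pts)
        t[1:-1] = pts[2:] - pts[:-2]
        t[0] = pts[1] - pts[0]
        t[-1] = pts[-1] - pts[-2]
    else:
        t = np.array(tangents, dtype=float)
    t /= np.linalg.norm(t, axis=1, keepdims=True)

    u = np.empty_like(pts)
    # deterministic seed normal: any direction not parallel to t[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u0 = ref - (ref @ t[0]) * t[0]
    u[0] = u0 / np.linalg.norm(u0)
    for i in range(n - 1):
        v1 = pts[i + 1] - pts[i]
        c1 = v1 @ v1
        if c1 < 1e-30:
            u[i + 1] = u[i]
            continue
        uL = u[i] - (2.0 / c1) * (v1 @ u[i]) * v1
        tL = t[i] - (2.0 / c1) * (v1 @ t[i]) * v1
        v2 = t[i + 1] - tL
        c2 = v2 @ v2
        if c2 < 1e-30:
            u[i + 1] = uL
        else:
            u[i + 1] = uL - (2.0 / c2) * (v2 @ uL) * v2
        # re-orthonormalise against accumulated drift
        u[i + 1] -= (u[i + 1] @ t[i + 1]) * t[i + 1]
        u[i + 1] /= np.linalg.norm(u[i + 1])
    v = np.cross(t, u)
    return t, u, v
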