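"""Four-grade area quantization and the preferential-initiation vote.

For each indicator (TAWSS, AFI, GON) on one inception region, the values
of the both-removed model ("pre") and the one-removed model ("post") are
pooled, the pooled range is split into four equal-width grades, and the
wall area falling in the risk grade (top grade for TAWSS and GON, bottom
grade for AFI, whose risk factor is strongly negative values) is summed
from the triangle fragments.  The area-changing ratio

    ratio = (risk_area_post - risk_area_pre) / risk_area_pre

measures how much the risky wall area of the region grows when the other
aneurysm is present.  The model (P or D) whose region shows the larger
ratio wins that indicator; two or more of the three indicators must
agree to call a possible preferential-initiation model, otherwise the
case is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import RoiPatch, ValidationError

__all__ = ["GradingResult", "CaseVerdict", "grade_field", "vote_preferential", "case_report"]

N_GRADES = 4
DEGENERATE_FLOOR = 1e-6  # of patch area, floor for an empty pre risk area
RISK_DIRECTIONS = {"TAWSS": "high", "AFI": "low", "GON": "high"}


@dataclass
class GradingResult:
    indicator: str
    risk_direction: str  # "high": top grade is risky; "low": bottom grade
    bin_edges: np.ndarray  # 5 ascending values spanning the pooled range
    risk_area_pre: float
    risk_area_post: float
    patch_area: float
    ratio: float
    degenerate_flag: bool

    def to_dict(self) -> dict:
        return {
            "indicator": self.indicator,
            "risk_direction": self.risk_direction,
            "bin_edges": self.bin_edges.tolist(),
            "risk_area_pre": self.risk_area_pre,
            "risk_area_post": self.risk_area_post,
            "patch_area": self.patch_area,
            "ratio": self.ratio,
            "degenerate_flag": self.degenerate_flag,
        }


@dataclass
class CaseVerdict:
    winners: dict  # indicator -> "P" | "D" | "tie"
    overall: str  # "P" | "D" | "indeterminate"
    votes: dict  # {"P": k, "D": k}

    def to_dict(self) -> dict:
        return {"winners": self.winners, "overall": self.overall, "votes": self.votes}


def _triangle_values(values: np.ndarray, roi: RoiPatch) -> np.ndarray:
    """Triangle fragment value = mean of its three vertex values."""
    return values[roi.mesh.triangles[roi.triangle_ids]].mean(axis=1)


def grade_field(
    field_pre: np.ndarray,
    field_post: np.ndarray,
    roi: RoiPatch,
    risk_direction: str = "high",
    indicator: str = "",
) -> GradingResult:
    """Grade one indicator on one ROI for the pre/post model pair.

    ``field_pre`` / ``field_post`` are per-vertex values on meshes
    sharing the ROI's triangulation (vertex correspondence given).
    """
    if risk_direction not in ("high", "low"):
        raise ValidationError("risk_direction must be 'high' or 'low'")
    tri_pre = _triangle_values(np.asarray(field_pre, float), roi)
    tri_post = _triangle_values(np.asarray(field_post, float), roi)
    areas = roi.mesh.triangle_areas()[roi.triangle_ids]
    patch_area = float(areas.sum())

    lo = min(tri_pre.min(), tri_post.min())
    hi = max(tri_pre.max(), tri_post.max())
    if hi - lo < 1e-30 * max(1.0, abs(hi)):
        raise ValidationError("ungradeable: pooled field is constant on the ROI")
    edges = np.linspace(lo, hi, N_GRADES + 1)

    if risk_direction == "high":
        risk_pre = tri_pre > edges[-2]
        risk_post = tri_post > edges[-2]
    else:
        risk_pre = tri_pre < edges[1]
        risk_post = tri_post < edges[1]
    # the pooled extremes themselves always grade as risky
    if risk_direction == "high":
        risk_pre |= tri_pre >= hi
        risk_post |= tri_post >= hi
    else:
        risk_pre |= tri_pre <= lo
        risk_post |= tri_post <= lo

    area_pre = float(areas[risk_pre].sum())
    area_post = float(areas[risk_post].sum())
    floor = DEGENERATE_FLOOR * patch_area
    degenerate = area_pre < floor
    denom = max(area_pre, floor)
    ratio = (area_post - area_pre) / denom
    return GradingResult(
        indicator=indicator,
        risk_direction=risk_direction,
        bin_edges=edges,
        risk_area_pre=area_pre,
        risk_area_post=area_post,
        patch_area=patch_area,
        ratio=float(ratio),
        degenerate_flag=bool(degenerate),
    )


def vote_preferential(ratios_P: dict, ratios_D: dict, tie_tol: float = 1e-9) -> CaseVerdict:
    """Majority vote over the three indicators' area-changing ratios.

    ``ratios_P`` are computed on the proximal inception region (Surface A
    of Model P), ``ratios_D`` on the distal one (Surface B of Model D).
    Each indicator votes for the side with the strictly larger ratio; the
    overall call needs at least 2 of 3 agreeing votes.
    """
    required = ("TAWSS", "AFI", "GON")
    for name in required:
        if name not in ratios_P or name not in ratios_D:
            raise ValidationError(f"missing indicator {name}")
    winners = {}
    votes = {"P": 0, "D": 0}
    for name in required:
        diff = float(ratios_P[name]) - float(ratios_D[name])
        if abs(diff) < tie_tol:
            winners[name] = "tie"
        elif diff > 0:
            winners[name] = "P"
            votes["P"] += 1
        else:
            winners[name] = "D"
            votes["D"] += 1
    if votes["P"] >= 2:
        overall = "P"
    elif votes["D"] >= 2:
        overall = "D"
    else:
        overall = "indeterminate"
    return CaseVerdict(winners=winners, overall=overall, votes=votes)


def case_report(
    morphology_block: dict | None = None,
    grading_P: dict | None = None,
    grading_D: dict | None = None,
    vortex_block: dict | None = None,
    verdict: CaseVerdict | None = None,
    config: dict | None = None,
) -> dict:
    """Assemble the per-case structured report.

    Layout: a morphology block (curvature summaries + DM), a grading
    block with per-indicator ratios for Model P and Model D, an optional
    vortex block (component counts, volumes, ROI distances), and the
    verdict.  Missing stages are recorded as null rather than omitted.
    """
    gradings = None
    if grading_P is not None or grading_D is not None:
        gradings = {
            "model_P": {k: v.to_dict() if isinstance(v, GradingResult) else v for k, v in (grading_P or {}).items()},
            "model_D": {k: v.to_dict() if isinstance(v, GradingResult) else v for k, v in (grading_D or {}).items()},
        }
    if verdict is None and gradings is not None and grading_P and grading_D:
        verdict = vote_preferential(
            {k: v.ratio for k, v in grading_P.items()}, {k: v.ratio for k, v in grading_D.items()}
        )
    return {
        "morphology": morphology_block,
        "grading": gradings,
        "vortex": vortex_block,
        "verdict": verdict.to_dict() if verdict is not None else None,
        "config": config,
    }
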