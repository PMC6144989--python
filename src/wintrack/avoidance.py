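"""Developed-recreation (ski-area) avoidance analyses.

A Monte-Carlo bootstrap tests whether an animal entered a developed
ski-area polygon less (or more) often than a uniform user of its 95%
MCP home range would, and a logistic GLMM models the probability that a
fix falls inside the ski boundary as a function of month, weekend,
night and canopy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .models import ModelSpec, cv_auc, fit_mixed, rank_aicc
from .selection import sample_available

AVOIDANCE = "avoidance"
PREFERENCE = "preference"
NO_DIFFERENCE = "no_difference"


def classify_count(n_inside: int, lower: float, upper: float) -> str:
    """Classify an observed inside-polygon count against a bootstrap
    interval: below the lower 2.5% bound = avoidance, above the upper
    97.5% bound = preference, otherwise no difference."""
    if lower > upper:
        raise ValueError("lower bound exceeds upper bound")
    if n_inside < lower:
        return AVOIDANCE
    if n_inside > upper:
        return PREFERENCE
    return NO_DIFFERENCE


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    """Nearest-rank empirical quantile (no interpolation)."""
    n = len(sorted_vals)
    idx = max(int(np.ceil(q * n)) - 1, 0)
    return float(sorted_vals[idx])


@dataclass
class AvoidanceResult:
    """Bootstrap comparison of ski-area use for one animal-year."""

    animal_id: str
    n_total: int
    n_inside: int
    lower: float
    upper: float
    classification: str
    overlap_share: float
    bootstrap_counts: np.ndarray
    note: str = ""


def overlap_share(mcp: Polygon, ski: Polygon) -> float:
    """Fraction of the home-range polygon covered by the ski polygon."""
    if mcp.area == 0:
        raise ValueError("zero-area home range")
    return float(mcp.intersection(ski).area / mcp.area)


def bootstrap_ski_test(
    fixes_xy: np.ndarray,
    mcp: Polygon,
    ski: Polygon,
    iterations: int = 1000,
    rng: np.random.Generator | None = None,
    animal_id: str = "",
) -> AvoidanceResult:
    """Monte-Carlo test of ski-area use against random expectation.

    Each iteration draws ``n_total`` (the animal's fix count) uniform
    points in the 95% MCP and counts how many fall inside the ski
    polygon; the 2.5 and 97.5 nearest-rank percentiles of the 1,000
    counts bracket random expectation.  The observed inside count below
    the lower bound indicates avoidance, above the upper bound
    preference.  An empty MCP-ski intersection is degenerate (expected
    count 0): classification is forced to no-difference with a note.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    fixes_xy = np.asarray(fixes_xy, dtype=float).reshape(-1, 2)
    n_total = len(fixes_xy)
    n_inside = int(shapely.contains_xy(ski, fixes_xy[:, 0], fixes_xy[:, 1]).sum())
    share = overlap_share(mcp, ski)
    if share == 0.0:
        return AvoidanceResult(
            animal_id, n_total, n_inside, 0.0, 0.0, NO_DIFFERENCE, 0.0,
            np.zeros(iterations, dtype=int),
            note="MCP does not intersect the ski polygon; test degenerate",
        )
    # draw all iterations at once: uniform in MCP, count inside ski
    pts = sample_available(mcp, n_total * iterations, ratio=1, rng=rng)
    inside = shapely.contains_xy(ski, pts[:, 0], pts[:, 1])
    counts = inside.reshape(iterations, n_total).sum(axis=1)
    srt = np.sort(counts)
    lower = _nearest_rank(srt, 0.025)
    upper = _nearest_rank(srt, 0.975)
    return AvoidanceResult(
        animal_id,
        n_total,
        n_inside,
        lower,
        upper,
        classify_count(n_inside, lower, upper),
        share,
        counts,
    )


def avoidance_table(results: list[AvoidanceResult]) -> pd.DataFrame:
    """Summary table mirroring the per-animal bootstrap report."""
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in results],
            "n_total": [r.n_total for r in results],
            "n_inside": [r.n_inside for r in results],
            "lower_ci": [r.lower for r in results],
            "upper_ci": [r.upper for r in results],
            "classification": [r.classification for r in results],
            "overlap_share": [r.overlap_share for r in results],
        }
    )


def ski_candidate_sets() -> dict[str, list[str]]:
    """Default 11-model candidate set for the ski-area entry model.

    All models share the canopy base (habitat control); additive and
    interactive combinations of month (continuous), weekend and night
    reflect how human use of a resort varies through the season and
    week.
    """
    return {
        "canopy": ["canopy"],
        "canopy+month": ["canopy", "month"],
        "canopy+weekend": ["canopy", "weekend"],
        "canopy+night": ["canopy", "night"],
        "canopy+month+weekend": ["canopy", "month", "weekend"],
        "canopy+month+night": ["canopy", "month", "night"],
        "canopy+weekend+night": ["canopy", "weekend", "night"],
        "canopy+month+weekend+night": ["canopy", "month", "weekend", "night"],
        "canopy+month*weekend": ["canopy", "month", "weekend", "month:weekend"],
        "canopy+month*night": ["canopy", "month", "night", "month:night"],
        "canopy+month*weekend+night": [
            "canopy",
            "month",
            "weekend",
            "night",
            "month:weekend",
        ],
    }


def fit_ski_use_model(
    table: pd.DataFrame,
    candidate_sets: dict[str, list[str]] | None = None,
    cv: bool = True,
    seed: int = 0,
    n_quad: int = 25,
) -> dict:
    """AICc-ranked logistic GLMMs of fix-inside-ski-area probability.

    ``table`` needs columns ``inside`` (0/1), ``month`` (continuous,
    February = 2 ... June = 6), ``weekend`` (0/1), ``night`` (0/1),
    ``canopy`` and ``animal_id``.  Errors when no fix of any animal is
    inside the polygon (the model is unidentifiable).
    """
    if table["inside"].sum() == 0:
        raise ValueError("no fixes inside the ski polygon: model unidentifiable")
    data = table.copy()
    if data["canopy"].std() > 0:
        data["canopy"] = (data["canopy"] - data["canopy"].mean()) / data["canopy"].std()
    sets = candidate_sets if candidate_sets is not None else ski_candidate_sets()
    fits = []
    for label, terms in sets.items():
        spec = ModelSpec(
            response="inside",
            terms=terms,
            group="animal_id",
            family="binomial",
            label=label,
        )
        fits.append(fit_mixed(spec, data, n_quad=n_quad))
    ranking = rank_aicc(fits)
    best = ranking["fit"].iloc[0]
    out = {"ranking": ranking.drop(columns="fit"), "best": best, "data": data}
    if cv:
        out["cv_auc"] = cv_auc(best.spec, data, k=5, seed=seed, n_quad=n_quad)
    return out


def predicted_use_ratio(
    fit, month_a: float, month_b: float, weekend: int, night: int = 0, canopy: float = 0.0
) -> float:
    """Ratio P(inside | month_a, stratum) / P(inside | month_b, stratum)
    at fixed weekend/night/canopy values -- e.g. June-weekend use
    relative to February-weekend use."""
    rows = pd.DataFrame(
        {
            "month": [month_a, month_b],
            "weekend": weekend,
            "night": night,
            "canopy": canopy,
            "inside": 0,
        }
    )
    p = fit.predict_fixed(rows)
    if p[1] == 0:
        return np.inf
    return float(p[0] / p[1])
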