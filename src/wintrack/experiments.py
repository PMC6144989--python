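"""Operating-characteristic experiments on synthetic scenarios.

Each experiment regenerates data with known ground truth and measures
how well the corresponding estimator recovers it: RSF coefficient
recovery and CI coverage, null calibration and power of the bootstrap
ski-area test, activity-classifier state recovery, and power / size of
the functional-response likelihood-ratio test.  The tests and the
acceptance script both run these, so the numbers they report are always
recomputed from scratch.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .avoidance import AVOIDANCE, bootstrap_ski_test
from .models import ModelSpec, fit_mixed
from .movement import ActivityClassifier
from .recsurface import IntensitySurface
from .selection import build_use_available_table, functional_response
from .synth import (
    STATIONARY_JITTER_SD,
    ScenarioConfig,
    generate_scenario,
    make_stationary_collar_points,
    make_two_state_track,
)


def rsf_recovery_once(seed: int, beta: float = -1.0, n_animals: int = 10,
                      n_days: int = 14, n_quad: int = 9,
                      cluster_robust: bool | str = False) -> dict:
    """One seed of the RSF parameter-recovery experiment.

    Generates a scenario with ``beta_avoid[snowmobile] = beta`` (log-odds
    per SD of extent-standardized 1-km snowmobile intensity), builds the
     1:2 used-available table per animal-year on that same standardized
    intensity scale, and fits the univariate weighted logistic GLMM with
    an animal random intercept.  Returns the fitted coefficient and its
    Wald CI (pass ``cluster_robust='jackknife'`` for CIs that honour the
    serial dependence of fixes; the point estimate is unaffected).
    """
    cfg = ScenarioConfig(
        seed=seed, n_animals=n_animals, n_days=n_days,
        activity_types=("snowmobile",),
        beta_avoid={"snowmobile": beta},
    )
    sc = generate_scenario(cfg, radii=(1000.0,))
    # covariate on the generator's own scale: extent-standardized intensity
    zsurf = {
        "snowmobile": IntensitySurface(
            sc.intensity_z["snowmobile"], cfg.grid, 1000.0, "snowmobile", cfg.year
        )
    }
    rng = np.random.default_rng(seed + 100_000)
    # availability = the generator's true home-range circles, so the
    # estimand matches the generating coefficient exactly (estimating
    # the domain with an MCP from 1,000 autocorrelated fixes adds a
    # known hull-truncation attenuation; see docs/methods.md)
    hr = cfg.home_range_radius
    centers = sc.truth.home_range_centers
    domains = {
        (row.animal_id, cfg.year): Point(row.cx, row.cy).buffer(hr, 64)
        for row in centers.itertuples()
    }
    table = build_use_available_table(sc.fixes, zsurf, rng=rng, domains=domains)
    spec = ModelSpec(
        response="used", terms=["intensity_snowmobile"], group="animal_id",
        family="binomial", weights="weight", label="recovery",
    )
    fit = fit_mixed(spec, table, n_quad=n_quad, cluster_robust=cluster_robust)
    est = float(fit.params["intensity_snowmobile"])
    lo, hi = fit.conf_int.loc["intensity_snowmobile"]
    return {"seed": seed, "beta_true": beta, "beta_hat": est,
            "ci_lower": float(lo), "ci_upper": float(hi),
            "covers_truth": bool(lo <= beta <= hi)}


def rsf_recovery_experiment(n_seeds: int = 100, beta: float = -1.0, seed0: int = 0,
                            **kw) -> pd.DataFrame:
    rows = [rsf_recovery_once(seed0 + s, beta, **kw) for s in range(n_seeds)]
    return pd.DataFrame(rows)


def _square(x0: float, y0: float, side: float) -> Polygon:
    return Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])


def bootstrap_null_experiment(
    n_replicates: int = 200, n_total: int = 1000, overlap: float = 0.15,
    iterations: int = 1000, seed0: int = 0,
) -> dict:
    """Type-I calibration of the ski-area bootstrap test.

    A uniform user of a square home range that overlaps the ski polygon
    by ``overlap`` should be classified 'avoidance' in about 2.5% of
    replicates (the lower-tail mass of the bootstrap interval).
    """
    side = 4000.0
    mcp = _square(0, 0, side)
    ski_side = side * np.sqrt(overlap)
    ski = _square(side - ski_side, 0, ski_side)
    labels = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed0 + r)
        fixes = rng.uniform(0, side, size=(n_total, 2))
        res = bootstrap_ski_test(fixes, mcp, ski, iterations=iterations, rng=rng)
        labels.append(res.classification)
    labels = np.asarray(labels)
    return {
        "avoidance_rate": float((labels == AVOIDANCE).mean()),
        "n_replicates": n_replicates,
    }


def bootstrap_exclusion_experiment(
    n_replicates: int = 200, n_total: int = 1000, overlap: float = 0.15,
    iterations: int = 1000, seed0: int = 0,
) -> dict:
    """Power of the bootstrap test against hard ski-area exclusion: an
    animal that never enters the polygon while using the rest of its
    home range uniformly."""
    side = 4000.0
    mcp = _square(0, 0, side)
    ski_side = side * np.sqrt(overlap)
    ski = _square(side - ski_side, 0, ski_side)
    labels = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed0 + 10_000 + r)
        pts = np.empty((0, 2))
        while len(pts) < n_total:
            cand = rng.uniform(0, side, size=(2 * n_total, 2))
            keep = ~shapely.contains_xy(ski, cand[:, 0], cand[:, 1])
            pts = np.vstack([pts, cand[keep]])
        fixes = pts[:n_total]
        res = bootstrap_ski_test(fixes, mcp, ski, iterations=iterations, rng=rng)
        labels.append(res.classification)
    labels = np.asarray(labels)
    return {
        "avoidance_rate": float((labels == AVOIDANCE).mean()),
        "n_replicates": n_replicates,
    }


def classifier_experiment(
    n_fixes: int = 5000, p_active: float = 0.6, seed: int = 0
) -> dict:
    """Calibrate on stationary collars, classify a two-state track whose
    stationary jitter matches the calibration fixture, and report state
    recovery plus the calibrated step threshold against the analytic
    Rayleigh 70th percentile."""
    rng = np.random.default_rng(seed)
    collars = make_stationary_collar_points(rng=rng)
    clf = ActivityClassifier().fit(collars)
    track = make_two_state_track(n_fixes=n_fixes, p_active=p_active, rng=rng)
    states = clf.predict(track)
    acc = float((states == track["state_true"].to_numpy()).mean())
    analytic_q70 = STATIONARY_JITTER_SD * np.sqrt(2.0) * np.sqrt(-2.0 * np.log(0.3))
    return {
        "state_recovery": acc,
        "step_threshold": float(clf.step_threshold_),
        "analytic_step_q70": float(analytic_q70),
        "turn_band_lower": float(clf.turn_band_[0]),
        "n_fixes": n_fixes,
    }


def _fr_table(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Wrap per-individual (availability, use) means as the table
    functional_response expects."""
    rows = []
    for i, (xa, ya) in enumerate(zip(x, y)):
        rows.append({"animal_id": f"I{i:02d}", "year": 2012, "used": 1,
                     "intensity_sim": ya})
        rows.append({"animal_id": f"I{i:02d}", "year": 2012, "used": 0,
                     "intensity_sim": xa})
    return pd.DataFrame(rows)


def functional_response_power_experiment(
    n_replicates: int = 200, n_individuals: int = 20, quad_coef: float = 2.0,
    noise_sd: float = 0.1, seed0: int = 0, alpha: float = 0.05,
) -> dict:
    """Power of the functional-response LRT against a quadratic truth,
    and its size under a linear truth with slope exactly 1."""
    rng = np.random.default_rng(seed0)
    reject_quad = 0
    reject_null = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_replicates):
            x = rng.uniform(0.1, 1.0, n_individuals)
            y_quad = 0.1 + x - quad_coef * x**2 + rng.normal(0, noise_sd, n_individuals)
            res = functional_response(_fr_table(x, y_quad), "sim")
            reject_quad += res["lrt_p"] < alpha
            y_lin = x + rng.normal(0, noise_sd, n_individuals)
            res0 = functional_response(_fr_table(x, y_lin), "sim")
            reject_null += res0["lrt_p"] < alpha
    return {
        "power_quadratic": reject_quad / n_replicates,
        "size_linear": reject_null / n_replicates,
        "n_replicates": n_replicates,
        "n_individuals": n_individuals,
    }
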