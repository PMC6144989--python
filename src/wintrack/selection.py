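"""Used-available selection analyses within home ranges.

Builds third-order (within-home-range) used-available tables at a 1:2
ratio, screens trail-covariate scales, fits AICc-ranked candidate RSF
models per recreation type, models diel activity against recreation
intensity, and estimates functional responses and selection ratios
across individuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy import stats as sps
from shapely.geometry import Polygon

from .models import FitResult, ModelSpec, Standardizer, cv_auc, fit_mixed, rank_aicc
from .movement import mcp_home_range
from .recsurface import IntensitySurface, TrailSet, candidate_trail_forms, trail_covariate
from .solar import solar_period


def sample_available(
    polygon: Polygon, n_used: int, ratio: int = 2, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Uniform random points inside a polygon by rejection sampling.

    Returns ``ratio * n_used`` points as an (m, 2) array.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if polygon.is_empty or polygon.area == 0:
        raise ValueError("degenerate availability polygon")
    n = int(ratio * n_used)
    xmin, ymin, xmax, ymax = polygon.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(64, int((n - filled) / max(polygon.area / ((xmax - xmin) * (ymax - ymin)), 1e-6) * 1.2))
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        keep = shapely.contains_xy(polygon, xs, ys)
        k = min(int(keep.sum()), n - filled)
        out[filled : filled + k, 0] = xs[keep][:k]
        out[filled : filled + k, 1] = ys[keep][:k]
        filled += k
    return out


def build_use_available_table(
    fixes: pd.DataFrame,
    surfaces: dict[str, IntensitySurface],
    trails: dict[str, TrailSet] | None = None,
    canopy: np.ndarray | None = None,
    grid=None,
    ratio: int = 2,
    rng: np.random.Generator | None = None,
    reference_latlon: tuple[float, float] = (39.45, -106.30),
    mcp_level: float = 95.0,
    domains: dict | None = None,
) -> pd.DataFrame:
    """Used (1) and available (0) locations with covariates and weights.

    Per animal-year: fixes inside the 95% MCP are the used sample;
    ``ratio`` times as many uniform points in the MCP are the available
    sample.  ``domains`` may supply a known availability polygon per
    ``(animal_id, year)`` (e.g. the synthetic generator's true
    home-range circle, for parameter-recovery experiments); the MCP
    estimated from the fixes is then bypassed.  Estimating the domain
    from the fixes is the field design, but with short tracks the hull
    truncates rarely-used (avoided) habitat and attenuates selection
    coefficients toward zero.  Available points get a random hour (uniform on [0, 24) on a
    randomly chosen fix date) mapped through sunrise/sunset to a
    day/night period, enabling temporal terms.  Covariates: per-type
    intensity (``intensity_<type>``), per-type trail distance
    (``dist_trail_<type>``; NaN for an empty/absent trail set), canopy.
    Weights: 1 for used, ``1/ratio`` for available, so the two classes
    contribute equal total weight.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    lat, lon = reference_latlon
    frames = []
    year_col = fixes["year"] if "year" in fixes.columns else 0
    for (animal, year), g in fixes.groupby(["animal_id", year_col]):
        pts = g[["x", "y"]].to_numpy()
        if domains is not None and (animal, year) in domains:
            mcp = domains[(animal, year)]
        else:
            mcp = mcp_home_range(pts, mcp_level)
        inside = shapely.contains_xy(mcp, pts[:, 0], pts[:, 1])
        used = g.loc[inside]
        n_used = len(used)
        if n_used == 0:
            continue
        avail_xy = sample_available(mcp, n_used, ratio, rng)
        dates = pd.DatetimeIndex(used["timestamp"]).normalize()
        rand_dates = rng.choice(dates.to_numpy(), size=len(avail_xy))
        rand_hours = rng.uniform(0, 24, size=len(avail_xy))
        avail_ts = pd.DatetimeIndex(rand_dates) + pd.to_timedelta(rand_hours, unit="h")

        def _block(xy, ts, used_flag, extra=None):
            d = pd.DataFrame(
                {
                    "animal_id": animal,
                    "year": year,
                    "used": used_flag,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "hour": pd.DatetimeIndex(ts).hour + pd.DatetimeIndex(ts).minute / 60.0,
                    "period": solar_period(ts, lat, lon),
                    "weight": 1.0 if used_flag else 1.0 / ratio,
                }
            )
            for meta in ("area", "sex"):
                if meta in g.columns:
                    d[meta] = g[meta].iloc[0]
            for atype, surf in surfaces.items():
                d[f"intensity_{atype}"] = surf.sample(xy[:, 0], xy[:, 1])
            if trails:
                for atype, tset in trails.items():
                    d[f"dist_trail_{atype}"] = tset.distance(xy[:, 0], xy[:, 1])
            if canopy is not None and grid is not None:
                d["canopy"] = grid.sample(canopy, xy[:, 0], xy[:, 1])
            return d

        frames.append(_block(used[["x", "y"]].to_numpy(), used["timestamp"], 1))
        frames.append(_block(avail_xy, avail_ts, 0))
    if not frames:
        raise ValueError("no usable animal-years")
    return pd.concat(frames, ignore_index=True)


def select_trail_scale(
    table: pd.DataFrame,
    activity_type: str,
    group: str = "animal_id",
    n_quad: int = 15,
    forms: list[tuple[str, float]] | None = None,
) -> dict | None:
    """Pick the trail covariate scale for one recreation type.

    Fits a univariate weighted logistic GLMM for each candidate form
    (default: binary 250/500/1000 m and decay alpha 50/100/250/500/2500)
    and returns the lowest-AICc form.  A single supplied candidate is
    returned unchanged.  Returns None (with a warning) when the type
    has no trail (all-NaN distances).
    """
    dist = table[f"dist_trail_{activity_type}"]
    if dist.isna().all():
        warnings.warn(f"no trails for {activity_type!r}; dropping trail covariates")
        return None
    forms = candidate_trail_forms() if forms is None else list(forms)
    if len(forms) == 1:
        return {"form": forms[0][0], "value": float(forms[0][1]), "ranking": None}
    fits = []
    sub = table.loc[dist.notna()].copy()
    for form, value in forms:
        col = f"_trail_{form}_{int(value)}"
        sub[col] = trail_covariate(sub[f"dist_trail_{activity_type}"], form, value)
        spec = ModelSpec(
            response="used",
            terms=[col],
            group=group,
            family="binomial",
            weights="weight",
            label=f"{form}:{value:g}",
        )
        fits.append(fit_mixed(spec, sub, n_quad=n_quad))
    ranking = rank_aicc(fits)
    best_label = ranking["label"].iloc[0]
    form, value = best_label.split(":")
    return {"form": form, "value": float(value), "ranking": ranking}


def rsf_candidate_sets(intensity: str, trail: str | None) -> dict[str, list[str]]:
    """Default RSF candidate model set per recreation type.

    Reconstructed from the main-text design: a canopy base model, then
    additive and interactive combinations of 1-km recreation intensity
    and trail proximity with canopy, study area and day/night period.
    ``trail=None`` (no-trail sentinel) keeps the intensity-only models.
    """
    sets = {
        "canopy": ["canopy"],
        "canopy+int": ["canopy", intensity],
        "canopy*int": ["canopy", intensity, f"canopy:{intensity}"],
        "canopy+int+area+int:area": ["canopy", intensity, "C(area)", f"{intensity}:C(area)"],
        "canopy+int+period+int:period": [
            "canopy",
            intensity,
            "C(period)",
            f"{intensity}:C(period)",
        ],
    }
    if trail is not None:
        sets.update(
            {
                "canopy+trail": ["canopy", trail],
                "canopy*trail": ["canopy", trail, f"canopy:{trail}"],
                "canopy+trail+area+trail:area": ["canopy", trail, "C(area)", f"{trail}:C(area)"],
                "canopy+trail+period+trail:period": [
                    "canopy",
                    trail,
                    "C(period)",
                    f"{trail}:C(period)",
                ],
                "canopy+int+trail": ["canopy", intensity, trail],
            }
        )
    return sets


def fit_rsf(
    table: pd.DataFrame,
    activity_type: str,
    trail_form: dict | None = None,
    candidate_sets: dict[str, list[str]] | None = None,
    standardize_covariates: bool = True,
    cv: bool = True,
    seed: int = 0,
    n_quad: int = 25,
) -> dict:
    """AICc-ranked used-available RSF for one recreation type.

    ``trail_form`` is the output of :func:`select_trail_scale` (or None
    for no trails).  Continuous covariates (intensity, canopy) are
    z-scored unless ``standardize_covariates=False`` (useful when the
    covariate is already on the scale the experiment defines).  Returns
    the ranking table, the best fit and its five-fold CV AUC.
    """
    data = table.copy()
    int_col = f"intensity_{activity_type}"
    trail_col = None
    if trail_form is not None:
        trail_col = "trail_cov"
        data[trail_col] = trail_covariate(
            data[f"dist_trail_{activity_type}"], trail_form["form"], trail_form["value"]
        )
        data = data.loc[data[trail_col].notna()]
    continuous = [c for c in (int_col, "canopy") if c in data.columns]
    scaler = None
    if standardize_covariates and continuous:
        cols = [c for c in continuous if data[c].std() > 0]
        if cols:
            scaler = Standardizer().fit(data[cols])
            data[cols] = scaler.transform(data[cols])
    if "canopy" not in data.columns:
        data["canopy"] = 0.0
    sets = candidate_sets if candidate_sets is not None else rsf_candidate_sets(int_col, trail_col)

    def _columns_of(terms: list[str]) -> set[str]:
        cols = set()
        for t in terms:
            for piece in t.split(":"):
                piece = piece.strip()
                if piece.startswith("C(") and piece.endswith(")"):
                    piece = piece[2:-1]
                cols.add(piece)
        return cols

    # keep only candidate models whose covariates the table carries
    sets = {k: v for k, v in sets.items() if _columns_of(v) <= set(data.columns)}
    if not sets:
        raise ValueError("no candidate model is estimable from the table's columns")
    fits = []
    for label, terms in sets.items():
        spec = ModelSpec(
            response="used",
            terms=terms,
            group="animal_id",
            family="binomial",
            weights="weight",
            label=label,
        )
        fits.append(fit_mixed(spec, data, n_quad=n_quad))
    ranking = rank_aicc(fits)
    best: FitResult = ranking["fit"].iloc[0]
    out = {"ranking": ranking.drop(columns="fit"), "best": best, "scaler": scaler, "data": data}
    if cv:
        out["cv_auc"] = cv_auc(best.spec, data, k=5, seed=seed, n_quad=n_quad)
    return out


def fit_temporal_activity(
    fix_table: pd.DataFrame,
    activity_type: str,
    min_stratum: int = 50,
    cv: bool = True,
    seed: int = 0,
    n_quad: int = 25,
) -> dict:
    """Diel activity versus recreation intensity, by area and period.

    Fits a logistic GLMM of active (1) / stationary (0) on standardized
    1-km intensity interacted with the combined area x period stratum
    (e.g. west-day, west-night, east-day, east-night), random intercept
    per animal.  Returns the fit, per-stratum predicted activity curves
    over the observed intensity range, and optional CV AUC.
    """
    data = fix_table.copy()
    if data["active"].nunique() < 2:
        raise ValueError("degenerate response: all fixes in one state")
    int_col = f"intensity_{activity_type}"
    if data[int_col].std() > 0:
        data["z_int"] = (data[int_col] - data[int_col].mean()) / data[int_col].std()
    else:
        data["z_int"] = 0.0
    if "area" in data.columns:
        data["stratum"] = data["area"].astype(str) + "_" + data["period"].astype(str)
    else:
        data["stratum"] = data["period"].astype(str)
    counts = data["stratum"].value_counts()
    small = counts[counts < min_stratum]
    if len(small):
        warnings.warn(f"strata with < {min_stratum} fixes kept: {dict(small)}")
    spec = ModelSpec(
        response="active",
        terms=["C(stratum)", "z_int", "z_int:C(stratum)"],
        group="animal_id",
        family="binomial",
        label=f"activity~intensity x stratum ({activity_type})",
    )
    fit = fit_mixed(spec, data, n_quad=n_quad)
    zgrid = np.linspace(data["z_int"].min(), data["z_int"].max(), 25)
    curves = {}
    for s in sorted(data["stratum"].unique()):
        pred = pd.DataFrame({"z_int": zgrid, "stratum": s, "active": 0})
        curves[s] = pd.DataFrame({"z_int": zgrid, "p_active": fit.predict_fixed(pred)})
    out = {"fit": fit, "curves": curves, "data": data}
    if cv:
        out["cv_auc"] = cv_auc(spec, data, k=5, seed=seed, n_quad=n_quad)
    return out


def mcp_mean_intensity(mcp: Polygon, surface: IntensitySurface) -> float:
    """Exhaustive availability: mean surface value over cells whose
    centers fall inside the home-range polygon."""
    cx, cy = surface.grid.center_coords()
    inside = shapely.contains_xy(mcp, cx, cy)
    if not inside.any():
        return np.nan
    return float(surface.values.ravel()[inside].mean())


def functional_response(
    table: pd.DataFrame,
    activity_type: str,
    availability: str = "sample",
    raster_means: dict | None = None,
    alpha: float = 0.05,
) -> dict:
    """Use versus availability across individuals (functional response).

    Per individual: mean 1-km intensity at used fixes (use) and at
    available points (availability; or exhaustive MCP raster means via
    ``availability='raster'`` with ``raster_means``).  Fits linear and
    quadratic OLS of use on availability and compares them with the
    exact likelihood-ratio test for nested gaussian models (the
    monotone F transform, df = 1), tests the linear slope against 1,
    and reports per-individual selection ratios (mean use / mean
    availability) plus a plot-ready table of (ratio - 1) against
    relative availability.  A functional response is supported when the
    quadratic wins the LRT or the linear slope differs from 1.
    """
    col = f"intensity_{activity_type}"
    per = []
    for (animal, year), g in table.groupby(["animal_id", "year"]):
        mean_used = g.loc[g["used"] == 1, col].mean()
        if availability == "raster":
            mean_avail = (raster_means or {}).get((animal, year), np.nan)
        else:
            mean_avail = g.loc[g["used"] == 0, col].mean()
        per.append({"animal_id": animal, "year": year, "mean_used": mean_used, "mean_available": mean_avail})
    per = pd.DataFrame(per)
    bad = per["mean_available"].isna() | (per["mean_available"] == 0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} individual(s) with zero/undefined availability"
        )
        per = per.loc[~bad]
    n = len(per)
    if n < 5:
        raise ValueError(f"need >= 5 individuals with positive availability, got {n}")
    x = per["mean_available"].to_numpy()
    y = per["mean_used"].to_numpy()
    X1 = sm.add_constant(x)
    X2 = sm.add_constant(np.column_stack([x, x**2]))
    lin = sm.OLS(y, X1).fit()
    quad = sm.OLS(y, X2).fit()
    lr_stat = 2.0 * (quad.llf - lin.llf)
    df_resid = n - 3
    rss1, rss2 = lin.ssr, quad.ssr
    if df_resid > 0 and rss2 > 0:
        F = (rss1 - rss2) / (rss2 / df_resid)
        lr_p = float(sps.f.sf(F, 1, df_resid))
    else:
        F, lr_p = np.inf, 0.0
    slope = lin.params[1]
    slope_se = lin.bse[1]
    t_slope = (slope - 1.0) / slope_se
    slope_p = float(2 * sps.t.sf(abs(t_slope), n - 2))
    per["selection_ratio"] = per["mean_used"] / per["mean_available"]
    per["ratio_minus_1"] = per["selection_ratio"] - 1.0
    per["relative_availability"] = per["mean_available"] / per["mean_available"].max()
    supported = (lr_p < alpha) or (slope_p < alpha)
    return {
        "individuals": per,
        "linear": lin,
        "quadratic": quad,
        "lrt_stat": float(lr_stat),
        "lrt_p": lr_p,
        "slope": float(slope),
        "slope_p_vs_1": slope_p,
        "r2_linear": float(lin.rsquared),
        "r2_quadratic": float(quad.rsquared),
        "functional_response_supported": bool(supported),
        "best_form": "quadratic" if lr_p < alpha else "linear",
    }
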