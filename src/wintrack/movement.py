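"""Movement annotation and summaries for collared animals.

Step lengths, absolute turn angles, active/stationary classification
calibrated from stationary test collars, solar day/night periods,
minimum-convex-polygon home ranges, movement rate and path tortuosity,
and the day/night period summary table that feeds the behavioral mixed
models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon
from sklearn.base import BaseEstimator

from .grid import GridSpec
from .solar import period_key, solar_period

#: default activity-rule thresholds measured from field stationary
#: collars: steps <= 27.02 m (70th pct) or turns in [174, 180] deg
#: (90th pct) mark a stationary fix.
DEFAULT_STEP_THRESHOLD = 27.02
DEFAULT_TURN_BAND = (174.0, 180.0)


def annotate_steps(fixes: pd.DataFrame, max_gap_intervals: float = 3.0) -> pd.DataFrame:
    """Add step/turn annotations to a fix table.

    Expects columns ``animal_id, timestamp, x, y`` (sorted or not).
    Adds ``step_length`` (m, from the previous fix), ``dt_hours``,
    ``turn_angle`` (deg in [0, 180]: absolute relative angle between the
    vectors t-1 -> t and t -> t+1) and ``burst`` (gaps longer than
    ``max_gap_intervals`` times the modal interval start a new burst;
    steps and turns are not computed across bursts).
    """
    df = fixes.sort_values(["animal_id", "timestamp"]).reset_index(drop=True).copy()
    out = []
    for _, g in df.groupby("animal_id", sort=False):
        g = g.copy()
        dt = g["timestamp"].diff().dt.total_seconds() / 3600.0
        interval = dt.dropna().mode()
        modal = interval.iloc[0] if len(interval) else np.nan
        new_burst = dt.isna() | (dt > max_gap_intervals * modal)
        g["burst"] = new_burst.cumsum()
        dx = g["x"].diff()
        dy = g["y"].diff()
        step = np.hypot(dx, dy)
        same_burst = g["burst"].diff().fillna(1) == 0
        g["step_length"] = np.where(same_burst, step, np.nan)
        g["dt_hours"] = np.where(same_burst, dt, np.nan)
        # heading of the incoming vector; turn at t compares t-1->t with t->t+1
        heading = np.arctan2(dy, dx)
        turn = np.abs(np.degrees(np.angle(np.exp(1j * (heading.shift(-1) - heading)))))
        valid = same_burst & same_burst.shift(-1).fillna(False).astype(bool)
        g["turn_angle"] = np.where(valid, turn, np.nan)
        out.append(g)
    return pd.concat(out, ignore_index=True)


class ActivityClassifier(BaseEstimator):
    """Active/stationary classifier calibrated on stationary collars.

    A fix is *stationary* when its step from the previous fix is at most
    the calibrated step threshold OR its turn angle falls inside the
    calibrated near-reversal band (both inclusive); otherwise *active*.
    The thresholds are the ``step_percentile`` of stationary-collar step
    lengths and the ``turn_percentile`` of stationary-collar turn angles
    (band upper edge anchored at 180 deg: GPS jitter of a motionless
    collar produces back-and-forth near-reversals).

    Without calibration data the classical field thresholds (27.02 m,
    174-180 deg) are used.
    """

    def __init__(self, step_percentile: float = 70.0, turn_percentile: float = 90.0,
                 step_threshold: float | None = None, turn_band: tuple[float, float] | None = None):
        self.step_percentile = step_percentile
        self.turn_percentile = turn_percentile
        self.step_threshold = step_threshold
        self.turn_band = turn_band

    def fit(self, stationary_fixes: pd.DataFrame, y=None):
        """Calibrate thresholds from stationary-collar fixes
        (``animal_id, timestamp, x, y``)."""
        ann = annotate_steps(stationary_fixes)
        steps = ann["step_length"].dropna()
        if len(steps) < 10:
            raise ValueError(
                f"need >= 10 stationary steps to calibrate, got {len(steps)}"
            )
        turns = ann["turn_angle"].dropna()
        self.step_threshold_ = float(np.percentile(steps, self.step_percentile))
        self.turn_band_ = (float(np.percentile(turns, self.turn_percentile)), 180.0)
        self.n_calibration_points_ = len(stationary_fixes)
        return self

    def _thresholds(self) -> tuple[float, tuple[float, float]]:
        if hasattr(self, "step_threshold_"):
            return self.step_threshold_, self.turn_band_
        step = DEFAULT_STEP_THRESHOLD if self.step_threshold is None else self.step_threshold
        band = DEFAULT_TURN_BAND if self.turn_band is None else self.turn_band
        return step, band

    def predict(self, fixes: pd.DataFrame) -> np.ndarray:
        """States ('active'/'stationary') per fix.

        ``fixes`` may be raw (annotated on the fly) or already carry
        ``step_length``/``turn_angle``.  The first fix of each burst has
        no step and inherits the following fix's state.
        """
        if "step_length" not in fixes.columns:
            fixes = annotate_steps(fixes)
        step_thr, band = self._thresholds()
        step = fixes["step_length"].to_numpy()
        turn = fixes["turn_angle"].to_numpy()
        stationary = (step <= step_thr) | ((turn >= band[0]) & (turn <= band[1]))
        states = np.where(stationary, "stationary", "active").astype(object)
        undefined = np.isnan(step)
        # first fix of a burst inherits the next fix's state
        for i in np.flatnonzero(undefined):
            states[i] = states[i + 1] if i + 1 < len(states) and not undefined[i + 1] else "active"
        return states.astype(str)


def classify_activity(fixes: pd.DataFrame, calibration: ActivityClassifier | None = None) -> np.ndarray:
    """Functional wrapper over :class:`ActivityClassifier.predict`."""
    clf = calibration if calibration is not None else ActivityClassifier()
    return clf.predict(fixes)


def mcp_home_range(points: np.ndarray, level: float = 95.0) -> Polygon:
    """Minimum convex polygon home range.

    At ``level`` 100 the convex hull of all points; at 95 the hull after
    discarding the ceil(5%) points farthest from the centroid of all
    points (centroid-distance peeling).  Collinear inputs yield a
    degenerate (zero-area) polygon and raise.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 5:
        raise ValueError("need >= 5 points for an MCP home range")
    if level not in (95.0, 100.0, 95, 100):
        raise ValueError("level must be 95 or 100")
    if level != 100:
        centroid = pts.mean(axis=0)
        d = np.hypot(*(pts - centroid).T)
        n_drop = int(np.ceil(len(pts) * (100.0 - level) / 100.0))
        keep = np.argsort(d)[: len(pts) - n_drop]
        pts = pts[keep]
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise ValueError("degenerate MCP: points are collinear")
    return hull


def movement_rate(steps: pd.DataFrame, states: np.ndarray | None = None,
                  method: str = "mean_speed") -> float:
    """Movement rate (km/hr) over the *active* steps of a period.

    ``method='mean_speed'`` (default) averages per-step speeds
    (step km / step hr); ``method='total'`` divides total active
    distance by total active time.  Returns NaN when no active step
    exists.
    """
    state = states if states is not None else steps["state"].to_numpy()
    mask = (state == "active") & steps["step_length"].notna().to_numpy() & (
        steps["dt_hours"].to_numpy() > 0
    )
    if not mask.any():
        return np.nan
    km = steps.loc[mask, "step_length"].to_numpy() / 1000.0
    hr = steps.loc[mask, "dt_hours"].to_numpy()
    if method == "mean_speed":
        return float(np.mean(km / hr))
    if method == "total":
        return float(km.sum() / hr.sum())
    raise ValueError(f"unknown method {method!r}")


def tortuosity(points: np.ndarray) -> float:
    """Straightness index in [0, 1]: net displacement over gross path
    length for the ordered fixes of a period.  NaN when the path length
    is zero or fewer than 2 fixes are given."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        return np.nan
    seg = np.hypot(*np.diff(pts, axis=0).T)
    total = seg.sum()
    if total == 0:
        return np.nan
    net = float(np.hypot(*(pts[-1] - pts[0])))
    return net / total


def build_period_table(
    fixes: pd.DataFrame,
    calibration: ActivityClassifier | None = None,
    surfaces: dict | None = None,
    canopy: np.ndarray | None = None,
    forest: np.ndarray | None = None,
    grid: GridSpec | None = None,
    reference_latlon: tuple[float, float] = (39.45, -106.30),
    mcp_level: float = 95.0,
    rate_method: str = "mean_speed",
) -> pd.DataFrame:
    """Day/night period summaries per animal-year.

    One row per animal-year x date x period with movement rate over
    active steps, tortuosity, period-averaged covariates (canopy,
    proportion forest, distance to forest edge, per-type intensity at
    the fixes), weekday/weekend flag, and any ``area``/``sex`` metadata
    columns.  Fixes outside the animal-year's 95% MCP are excluded
    before summarizing.  ``surfaces`` maps activity type ->
    :class:`~wintrack.recsurface.IntensitySurface` (1-km radius).
    """
    lat, lon = reference_latlon
    df = annotate_steps(fixes)
    df["state"] = classify_activity(df, calibration)
    pk = period_key(df["timestamp"], lat, lon)
    df["date"] = pk["date"].to_numpy()
    df["period"] = pk["period"].to_numpy()
    df["weekend"] = pd.DatetimeIndex(df["timestamp"]).dayofweek >= 5

    if forest is not None and grid is not None:
        from scipy.ndimage import distance_transform_edt

        f = forest.astype(bool)
        # distance to the forest/nonforest boundary from either side
        edge_dist = (distance_transform_edt(f) + distance_transform_edt(~f)) * grid.cell_size

    rows = []
    year_col = df["year"] if "year" in df.columns else pd.Series(0, index=df.index)
    for (animal, year), g in df.groupby(["animal_id", year_col]):
        try:
            mcp = mcp_home_range(g[["x", "y"]].to_numpy(), mcp_level)
        except ValueError:
            continue
        inside = shapely.contains_xy(mcp, g["x"].to_numpy(), g["y"].to_numpy())
        g = g.loc[inside]
        for (date, period), p in g.groupby(["date", "period"]):
            if len(p) == 0:
                continue
            row = {
                "animal_id": animal,
                "year": year,
                "date": date,
                "period": period,
                "n_fixes": len(p),
                "movement_rate": movement_rate(p, method=rate_method),
                "tortuosity": tortuosity(p[["x", "y"]].to_numpy()),
                "weekend": bool(p["weekend"].mode().iloc[0]),
            }
            for meta in ("area", "sex"):
                if meta in p.columns:
                    row[meta] = p[meta].iloc[0]
            x = p["x"].to_numpy()
            y = p["y"].to_numpy()
            if canopy is not None and grid is not None:
                ok = grid.contains(x, y)
                row["canopy"] = float(grid.sample(canopy, x, y)[ok].mean()) if ok.any() else np.nan
                row["covariates_missing"] = bool((~ok).any())
            if forest is not None and grid is not None:
                row["prop_forest"] = float(grid.sample(forest, x, y).mean())
                row["dist_forest_edge"] = float(grid.sample(edge_dist, x, y).mean())
            if surfaces:
                for atype, surf in surfaces.items():
                    row[f"intensity_{atype}"] = float(surf.sample(x, y).mean())
            rows.append(row)
    return pd.DataFrame(rows)
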