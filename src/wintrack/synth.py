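"""Synthetic winter-recreation scenarios with known ground truth.

Generates everything a field study of recreation--wildlife interaction
would collect, with every effect size known exactly so downstream
estimators have a recoverable target:

* an autocorrelated canopy raster and a binary forest raster;
* recreationist GPS tracks at 5-s spacing, mostly concentrated along
  trail polylines with cross-track jitter, plus dispersed free-roaming
  tracks, for up to four activity types (hybrid = snowmobile-assisted
  ski, snowmobile, backcountry ski, packed-trail ski);
* two-state (active/stationary) animal trajectories at a 20- or 30-min
  fix interval whose spatial selection and diel activity respond to
  recreation intensity with known coefficients;
* an optional developed ski-area polygon with its own avoidance strength.

The animal walk is a biased random walk sampled with a
Metropolis-Hastings correction: each active step proposes 24 candidate
headings at a random step length, weights candidates by
``exp(selection log-weight)``, and accepts with the ratio of local
proposal normalizers.  Its stationary density is therefore exactly
proportional to ``exp(sum_k beta_k * z_k(x))`` where ``z_k`` are the
standardized covariate fields -- so a used-available selection model fit
to the fixes estimates the generating ``beta_avoid`` directly.  Animals
are initialized from that stationary density (cell-weighted draw), so no
burn-in is required.  With every beta equal to zero the correction is a
no-op and the walk is an unbiased random walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit
from shapely.geometry import LineString, Polygon
import shapely

from .grid import GridSpec, standardize_field
from .solar import solar_period

ACTIVITY_TYPES = ("hybrid", "snowmobile", "backcountry_ski", "packed_trail_ski")

# typical travel speed (m/s) used to space 5-s recreation fixes
_SPEEDS = {
    "hybrid": 4.0,
    "snowmobile": 6.0,
    "backcountry_ski": 1.0,
    "packed_trail_ski": 1.3,
}

#: GPS jitter (m, per coordinate) of a stationary collar.  Chosen so the
#: 70th percentile of stationary step lengths (Rayleigh with scale
#: sd*sqrt(2)) sits at 27.02 m, the classical field calibration value.
STATIONARY_JITTER_SD = 27.02 / (np.sqrt(2.0) * np.sqrt(-2.0 * np.log(0.3)))


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    Defaults describe a single mid-winter study area: a 5 x 5 km extent
    at 30-m resolution, collars on a 20-min duty cycle for two weeks
    (1,008 fixes/animal), and 30 GPS-logged recreation tracks per
    activity type, 85% of which follow groomed/user-established trails.
    Selection coefficients are log-odds per SD of the (extent-wide
    standardized) 1-km intensity field; all default to zero (a null
    animal), experiments set them explicitly.
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 5000.0, 5000.0)
    cell_size: float = 30.0
    n_animals: int = 10
    fix_interval: int = 20  # minutes
    n_days: int = 14
    year: int = 2012
    start_date: str = "2012-01-15"
    activity_types: tuple[str, ...] = ACTIVITY_TYPES
    tracks_per_type: int = 30
    trail_fraction: float = 0.85
    trails_per_type: int = 3
    track_duration_min: float = 90.0
    cross_track_jitter_sd: float = 25.0
    beta_avoid: dict[str, float] = field(default_factory=dict)
    beta_canopy: float = 0.0
    beta_activity_day: float | dict[str, float] = 0.0
    activity_base: float = 0.6  # stationary-state share of time is 1 - this
    ski_polygon: Polygon | None = None
    ski_strength: float = 0.0  # log-weight added inside the ski polygon
    canopy_mean: float = 45.0
    canopy_sd: float = 15.0
    canopy_smooth_sigma: float = 10.0  # cells
    forest_cutoff: float = 30.0  # canopy % above which a cell is forest
    active_step_mean: float = 100.0  # m per movement substep
    active_step_shape: float = 2.0
    substeps_per_fix: int = 4  # movement substeps between recorded fixes
    stationary_jitter_sd: float = STATIONARY_JITTER_SD
    n_headings: int = 24
    home_range_radius: float | None = 1200.0  # m; None = free-roaming
    reference_latlon: tuple[float, float] = (39.45, -106.30)

    def __post_init__(self) -> None:
        if self.fix_interval not in (20, 30):
            raise ValueError("fix_interval must be 20 or 30 minutes")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.tracks_per_type < 0:
            raise ValueError("tracks_per_type must be >= 0")
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate extent")
        if (xmax - xmin) * (ymax - ymin) < 25e6:
            raise ValueError("extent area must be >= 25 km^2 so 1 km neighborhoods fit")
        unknown = set(self.activity_types) - set(ACTIVITY_TYPES)
        if unknown:
            raise ValueError(f"unknown activity types: {sorted(unknown)}")

    @property
    def grid(self) -> GridSpec:
        xmin, ymin, xmax, ymax = self.extent
        return GridSpec(xmin, ymin, xmax, ymax, self.cell_size)

    @property
    def fixes_per_animal(self) -> int:
        return int(self.n_days * 24 * 60 / self.fix_interval)


@dataclass
class GroundTruth:
    """What the generator actually did: one latent state per animal fix
    plus the true coefficient values used."""

    states: pd.DataFrame  # animal_id, fix, state (active/stationary)
    beta_avoid: dict[str, float]
    beta_canopy: float
    beta_activity_day: float | dict[str, float]
    ski_strength: float
    home_range_centers: pd.DataFrame | None = None  # animal_id, cx, cy


# ---------------------------------------------------------------------------
# landscape


def make_landscape(config: ScenarioConfig, rng: np.random.Generator | None = None):
    """Autocorrelated canopy (%) and binary forest rasters.

    Canopy is Gaussian white noise smoothed with a Gaussian kernel,
    rescaled to unit variance, then shifted/scaled to ``canopy_mean`` /
    ``canopy_sd`` and clipped to [0, 100].  ``canopy_sd = 0`` yields a
    constant raster.  Forest is ``canopy >= forest_cutoff``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    grid = config.grid
    noise = rng.normal(size=grid.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=config.canopy_smooth_sigma)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    canopy = np.clip(config.canopy_mean + config.canopy_sd * smooth, 0.0, 100.0)
    forest = (canopy >= config.forest_cutoff).astype(float)
    return canopy, forest


# ---------------------------------------------------------------------------
# recreation


def make_trail_polylines(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> dict[str, list[LineString]]:
    """Random smooth trail polylines per activity type.

    Each trail starts on one edge of the extent and performs a smoothed
    heading random walk until it leaves the extent (clipped back to it),
    emulating groomed routes and user-established skin tracks.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    xmin, ymin, xmax, ymax = config.extent
    trails: dict[str, list[LineString]] = {}
    for atype in config.activity_types:
        lines = []
        for _ in range(config.trails_per_type):
            side = rng.integers(4)
            if side == 0:
                x, y, heading = xmin, rng.uniform(ymin, ymax), 0.0
            elif side == 1:
                x, y, heading = xmax, rng.uniform(ymin, ymax), np.pi
            elif side == 2:
                x, y, heading = rng.uniform(xmin, xmax), ymin, np.pi / 2
            else:
                x, y, heading = rng.uniform(xmin, xmax), ymax, -np.pi / 2
            pts = [(x, y)]
            step = 100.0
            for _ in range(200):
                heading += rng.normal(0, 0.25)
                x += step * np.cos(heading)
                y += step * np.sin(heading)
                if not (xmin <= x <= xmax and ymin <= y <= ymax):
                    break
                pts.append((x, y))
            if len(pts) >= 2:
                lines.append(LineString(pts))
        trails[atype] = lines
    return trails


def _walk_along_line(line: LineString, speed: float, n_pts: int, jitter_sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Positions every 5 s travelling back and forth along a polyline."""
    length = line.length
    start = rng.uniform(0, length)
    direction = rng.choice([-1.0, 1.0])
    dists = start + direction * speed * 5.0 * np.arange(n_pts)
    # reflect within [0, length] (out-and-back travel)
    dists = np.abs(np.mod(dists, 2 * length))
    dists = np.where(dists > length, 2 * length - dists, dists)
    pts = shapely.line_interpolate_point(line, dists)
    xy = shapely.get_coordinates(pts)
    if jitter_sd > 0:
        xy = xy + rng.normal(0, jitter_sd, size=xy.shape)
    return xy


def make_recreation_tracks(
    config: ScenarioConfig,
    trails: dict[str, list[LineString]],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Recreationist GPS tracks at 5-s spacing.

    For each requested activity type, ``trail_fraction`` of tracks
    follow a trail polyline (out-and-back at the type's travel speed,
    with Gaussian cross-track jitter); the remainder are free heading
    random walks.  Returns a tidy frame with columns
    ``activity_type, track_id, year, timestamp, x, y``.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    xmin, ymin, xmax, ymax = config.extent
    n_pts = max(2, int(config.track_duration_min * 60 / 5))
    records = []
    t0 = pd.Timestamp(config.start_date, tz="UTC") + pd.Timedelta(hours=10)
    for atype in config.activity_types:
        type_trails = trails.get(atype, [])
        if config.tracks_per_type > 0 and config.trail_fraction > 0 and not type_trails:
            raise ValueError(
                f"activity type {atype!r} requested with trail_fraction > 0 but no trails"
            )
        speed = _SPEEDS[atype]
        for k in range(config.tracks_per_type):
            on_trail = rng.uniform() < config.trail_fraction
            if on_trail:
                line = type_trails[rng.integers(len(type_trails))]
                xy = _walk_along_line(line, speed, n_pts, config.cross_track_jitter_sd, rng)
            else:
                heading = rng.uniform(0, 2 * np.pi)
                x = rng.uniform(xmin, xmax)
                y = rng.uniform(ymin, ymax)
                xs, ys = [x], [y]
                for _ in range(n_pts - 1):
                    heading += rng.normal(0, 0.3)
                    x = np.clip(x + speed * 5.0 * np.cos(heading), xmin, xmax)
                    y = np.clip(y + speed * 5.0 * np.sin(heading), ymin, ymax)
                    xs.append(x)
                    ys.append(y)
                xy = np.column_stack([xs, ys])
            day = rng.integers(config.n_days)
            stamps = (
                t0
                + pd.Timedelta(days=int(day))
                + pd.to_timedelta(np.arange(len(xy)) * 5, unit="s")
            )
            records.append(
                pd.DataFrame(
                    {
                        "activity_type": atype,
                        "track_id": f"{atype}_{k:03d}",
                        "year": config.year,
                        "timestamp": stamps,
                        "x": xy[:, 0],
                        "y": xy[:, 1],
                    }
                )
            )
    if not records:
        return pd.DataFrame(
            columns=["activity_type", "track_id", "year", "timestamp", "x", "y"]
        )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# animals


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (assumes at most one bounce)."""
    v = np.where(v < lo, 2 * lo - v, v)
    v = np.where(v > hi, 2 * hi - v, v)
    return np.clip(v, lo, hi)


def _day_flags(config: ScenarioConfig, timestamps: pd.DatetimeIndex) -> np.ndarray:
    lat, lon = config.reference_latlon
    return solar_period(timestamps, lat, lon) == "day"


def make_animal_trajectories(
    config: ScenarioConfig,
    intensity_z: dict[str, np.ndarray],
    canopy: np.ndarray | None = None,
    ski_polygon: Polygon | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-state animal trajectories with known selection coefficients.

    Parameters
    ----------
    intensity_z
        Per-activity-type standardized 1-km intensity rasters (z-scored
        over the extent); selection operates on these fields.
    canopy
        Optional canopy raster; its z-field enters the selection
        log-weight with ``config.beta_canopy``.
    ski_polygon
        Overrides ``config.ski_polygon``; log-weight ``ski_strength``
        is added inside it (``-inf`` for hard exclusion).

    Returns the fix table (``animal_id, sex, area, timestamp, x, y,
    state_true``) and the :class:`GroundTruth`.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    grid = config.grid
    xmin, ymin, xmax, ymax = config.extent

    # selection log-weight field on the grid
    W = np.zeros(grid.shape)
    for atype, beta in config.beta_avoid.items():
        if atype not in intensity_z:
            raise ValueError(f"beta_avoid given for {atype!r} but no intensity surface")
        W = W + beta * intensity_z[atype]
    if canopy is not None and config.beta_canopy != 0.0:
        W = W + config.beta_canopy * standardize_field(canopy)
    ski = ski_polygon if ski_polygon is not None else config.ski_polygon
    if ski is not None and config.ski_strength != 0.0:
        cx, cy = grid.center_coords()
        inside = shapely.contains_xy(ski, cx, cy).reshape(grid.shape)
        W = W + np.where(inside, config.ski_strength, 0.0)

    # activity-modulation field: mean standardized intensity across types
    if intensity_z:
        z_rec = np.mean([intensity_z[t] for t in sorted(intensity_z)], axis=0)
    else:
        z_rec = np.zeros(grid.shape)

    n_fix = config.fixes_per_animal
    n_anim = config.n_animals
    timestamps = pd.date_range(
        pd.Timestamp(config.start_date, tz="UTC"),
        periods=n_fix,
        freq=f"{config.fix_interval}min",
    )
    is_day = _day_flags(config, timestamps)

    # territorial home ranges: animals are confined to circles whose
    # centers are spread over the extent, so selection is expressed
    # within a fixed availability domain (third-order selection)
    hr = config.home_range_radius
    if hr is not None:
        pad = min(hr, (xmax - xmin) / 2 - 1, (ymax - ymin) / 2 - 1)
        centers = np.column_stack(
            [
                rng.uniform(xmin + pad, xmax - pad, n_anim),
                rng.uniform(ymin + pad, ymax - pad, n_anim),
            ]
        )
    else:
        centers = None

    # initialize from the stationary density exp(W) (truncated to each
    # animal's home-range circle): weighted cell draw
    finiteW = np.where(np.isfinite(W), W, -np.inf)
    gx, gy = grid.center_coords()
    x = np.empty(n_anim)
    y = np.empty(n_anim)
    for i in range(n_anim):
        Wi = finiteW.ravel().copy()
        if centers is not None:
            outside = np.hypot(gx - centers[i, 0], gy - centers[i, 1]) > hr
            Wi[outside] = -np.inf
        p = np.exp(Wi - Wi.max())
        p = p / p.sum()
        cell = rng.choice(p.size, p=p)
        iy, ix = np.unravel_index(cell, grid.shape)
        x[i] = grid.xmin + (ix + rng.uniform()) * grid.cell_size
        y[i] = grid.ymin + (iy + rng.uniform()) * grid.cell_size

    areas = np.where(np.arange(n_anim) % 2 == 0, "west", "east")
    sexes = np.where(np.arange(n_anim) % 2 == 0, "F", "M")
    if isinstance(config.beta_activity_day, dict):
        b_act = np.array([config.beta_activity_day.get(a, 0.0) for a in areas])
    else:
        b_act = np.full(n_anim, float(config.beta_activity_day))
    base_logit = np.log(config.activity_base / (1 - config.activity_base))

    nh = config.n_headings
    scale = config.active_step_mean / config.active_step_shape
    X = np.empty((n_fix, n_anim))
    Y = np.empty((n_fix, n_anim))
    S = np.empty((n_fix, n_anim), dtype=bool)  # True = active
    X[0], Y[0] = x, y
    p_act0 = expit(base_logit + b_act * grid.sample(z_rec, x, y) * is_day[0])
    S[0] = rng.uniform(size=n_anim) < p_act0

    heads = 2 * np.pi * np.arange(nh) / nh

    def _mh_move(x, y, ai):
        """One MH-corrected biased substep for the animals indexed by ai."""
        m = ai.size
        L = rng.gamma(config.active_step_shape, scale, size=m)
        offs = rng.uniform(size=m)
        ang = heads[None, :] + 2 * np.pi * offs[:, None] / nh
        cx = _reflect(x[ai, None] + L[:, None] * np.cos(ang), xmin, xmax)
        cy = _reflect(y[ai, None] + L[:, None] * np.sin(ang), ymin, ymax)
        Wc = grid.sample(W, cx, cy)
        if centers is not None:
            d2 = np.hypot(cx - centers[ai, 0, None], cy - centers[ai, 1, None])
            Wc = np.where(d2 > hr, -np.inf, Wc)
        with np.errstate(over="ignore", invalid="ignore"):
            Wmax = Wc.max(axis=1)
            # weighted multinomial draw among the candidate headings
            probs = np.where(np.isfinite(Wc), np.exp(Wc - Wmax[:, None]), 0.0)
        probs_sum = probs.sum(axis=1, keepdims=True)
        ok = probs_sum[:, 0] > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            logC_x = Wmax + np.log(probs_sum[:, 0])
        probs = probs / np.where(probs_sum == 0, 1, probs_sum)
        u = rng.uniform(size=m)
        choice = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(max=nh - 1)
        px = cx[np.arange(m), choice]
        py = cy[np.arange(m), choice]
        # reverse candidate set at the proposal, anchored on the way back
        back = np.arctan2(y[ai] - py, x[ai] - px)
        rang = back[:, None] + heads[None, :]
        rx = _reflect(px[:, None] + L[:, None] * np.cos(rang), xmin, xmax)
        ry = _reflect(py[:, None] + L[:, None] * np.sin(rang), ymin, ymax)
        Wr = grid.sample(W, rx, ry)
        if centers is not None:
            d2r = np.hypot(rx - centers[ai, 0, None], ry - centers[ai, 1, None])
            Wr = np.where(d2r > hr, -np.inf, Wr)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            Wrmax = Wr.max(axis=1)
            logC_y = Wrmax + np.log(
                np.where(np.isfinite(Wr), np.exp(Wr - Wrmax[:, None]), 0.0).sum(axis=1)
            )
        accept = ok & (np.log(rng.uniform(size=m)) < logC_x - logC_y)
        x[ai] = np.where(accept, px, x[ai])
        y[ai] = np.where(accept, py, y[ai])

    for t in range(1, n_fix):
        z_here = grid.sample(z_rec, x, y)
        p_act = expit(base_logit + b_act * z_here * float(is_day[t]))
        active = rng.uniform(size=n_anim) < p_act

        if active.any():
            # the animal moves continuously between fixes: several
            # movement substeps per recorded fix
            ai = np.flatnonzero(active)
            for _ in range(config.substeps_per_fix):
                _mh_move(x, y, ai)
        # stationary animals: GPS jitter only
        si = np.flatnonzero(~active)
        if si.size:
            jitter = rng.normal(0, config.stationary_jitter_sd, size=(si.size, 2))
            x[si] = _reflect(x[si] + jitter[:, 0], xmin, xmax)
            y[si] = _reflect(y[si] + jitter[:, 1], ymin, ymax)
        X[t], Y[t] = x, y
        S[t] = active

    animal_ids = [f"A{i:02d}" for i in range(n_anim)]
    fixes = pd.DataFrame(
        {
            "animal_id": np.repeat(animal_ids, n_fix),
            "sex": np.repeat(sexes, n_fix),
            "area": np.repeat(areas, n_fix),
            "year": config.year,
            "timestamp": np.tile(timestamps, n_anim),
            "x": X.T.ravel(),
            "y": Y.T.ravel(),
            "state_true": np.where(S.T.ravel(), "active", "stationary"),
        }
    )
    truth = GroundTruth(
        states=fixes[["animal_id", "timestamp", "state_true"]].copy(),
        beta_avoid=dict(config.beta_avoid),
        beta_canopy=config.beta_canopy,
        beta_activity_day=config.beta_activity_day,
        ski_strength=config.ski_strength,
        home_range_centers=(
            pd.DataFrame(
                {"animal_id": animal_ids, "cx": centers[:, 0], "cy": centers[:, 1]}
            )
            if centers is not None
            else None
        ),
    )
    return fixes, truth


def default_ski_polygon(config: ScenarioConfig, share: float = 0.15) -> Polygon:
    """Square developed-area polygon covering ``share`` of the extent,
    placed against the eastern edge (mimics a resort adjacent to home
    ranges)."""
    xmin, ymin, xmax, ymax = config.extent
    area = (xmax - xmin) * (ymax - ymin) * share
    side = np.sqrt(area)
    cx = xmax - side / 2 - 0.05 * (xmax - xmin)
    cy = (ymin + ymax) / 2
    return Polygon(
        [
            (cx - side / 2, cy - side / 2),
            (cx + side / 2, cy - side / 2),
            (cx + side / 2, cy + side / 2),
            (cx - side / 2, cy + side / 2),
        ]
    )


# ---------------------------------------------------------------------------
# calibration / classifier fixtures


def make_stationary_collar_points(
    n_collars: int = 5,
    points_per_collar: int = 700,
    jitter_sd: float = STATIONARY_JITTER_SD,
    fix_interval: int = 20,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fixes from GPS collars left stationary in the field.

    Each collar sits at a fixed location; recorded positions are the
    location plus isotropic Gaussian GPS error.  Consecutive-position
    step lengths are then Rayleigh(``jitter_sd * sqrt(2)``), whose 70th
    percentile is 27.02 m at the default jitter.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    frames = []
    t0 = pd.Timestamp("2012-01-01", tz="UTC")
    for c in range(n_collars):
        center = rng.uniform(0, 10000, size=2)
        xy = center + rng.normal(0, jitter_sd, size=(points_per_collar, 2))
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": f"collar{c}",
                    "timestamp": t0 + pd.to_timedelta(
                        np.arange(points_per_collar) * fix_interval, unit="m"
                    ),
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_two_state_track(
    n_fixes: int = 2000,
    p_active: float = 0.6,
    active_step_mean: float = 210.0,
    active_step_shape: float = 2.0,
    heading_sd: float = 0.5,
    jitter_sd: float = STATIONARY_JITTER_SD,
    fix_interval: int = 20,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """A single two-state track for classifier validation.

    Active fixes move with persistent headings (wrapped-normal turning,
    sd ``heading_sd`` rad) and gamma step lengths; stationary fixes are
    pure GPS jitter matching the stationary-collar calibration fixture.
    States are independent Bernoulli(``p_active``) draws.  Returns
    columns ``animal_id, timestamp, x, y, state_true``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    states = rng.uniform(size=n_fixes) < p_active
    x = np.empty(n_fixes)
    y = np.empty(n_fixes)
    x[0], y[0] = 0.0, 0.0
    heading = rng.uniform(0, 2 * np.pi)
    scale = active_step_mean / active_step_shape
    for t in range(1, n_fixes):
        if states[t]:
            heading += rng.normal(0, heading_sd)
            L = rng.gamma(active_step_shape, scale)
            x[t] = x[t - 1] + L * np.cos(heading)
            y[t] = y[t - 1] + L * np.sin(heading)
        else:
            x[t] = x[t - 1] + rng.normal(0, jitter_sd)
            y[t] = y[t - 1] + rng.normal(0, jitter_sd)
    return pd.DataFrame(
        {
            "animal_id": "sim",
            "timestamp": pd.Timestamp("2012-01-15", tz="UTC")
            + pd.to_timedelta(np.arange(n_fixes) * fix_interval, unit="m"),
            "x": x,
            "y": y,
            "state_true": np.where(states, "active", "stationary"),
        }
    )


# ---------------------------------------------------------------------------
# full scenario


@dataclass
class Scenario:
    """Bundle of everything one synthetic study produced."""

    config: ScenarioConfig
    canopy: np.ndarray
    forest: np.ndarray
    trails: dict[str, list[LineString]]
    recreation: pd.DataFrame
    surfaces: dict  # (activity_type, radius) -> IntensitySurface
    intensity_z: dict[str, np.ndarray]
    fixes: pd.DataFrame
    truth: GroundTruth
    ski_polygon: Polygon | None


def generate_scenario(
    config: ScenarioConfig,
    with_ski: bool = False,
    radii: tuple[float, ...] = (100.0, 1000.0),
) -> Scenario:
    """Run the full generator: landscape, trails, recreation tracks,
    intensity surfaces at the requested radii (1 km drives selection;
    100 m feeds trail extraction), and animal trajectories."""
    from .recsurface import point_density

    if 1000.0 not in radii:
        raise ValueError("the 1 km surface is required (selection operates on it)")
    rng = np.random.default_rng(config.seed)
    canopy, forest = make_landscape(config, rng)
    trails = make_trail_polylines(config, rng)
    recreation = make_recreation_tracks(config, trails, rng)
    grid = config.grid
    surfaces = {}
    intensity_z = {}
    for atype in config.activity_types:
        pts = recreation.loc[recreation["activity_type"] == atype, ["x", "y"]].to_numpy()
        for radius in radii:
            surfaces[(atype, radius)] = point_density(
                pts, radius, grid, activity_type=atype, year=config.year
            )
        intensity_z[atype] = standardize_field(surfaces[(atype, 1000.0)].values)
    ski = config.ski_polygon
    if with_ski and ski is None:
        ski = default_ski_polygon(config)
    fixes, truth = make_animal_trajectories(config, intensity_z, canopy, ski, rng)
    return Scenario(
        config=config,
        canopy=canopy,
        forest=forest,
        trails=trails,
        recreation=recreation,
        surfaces=surfaces,
        intensity_z=intensity_z,
        fixes=fixes,
        truth=truth,
        ski_polygon=ski,
    )
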