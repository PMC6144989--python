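"""Recreation-intensity surfaces and trail covariates.

Converts recreationist GPS points into circular-neighborhood point
density rasters (points per square kilometer), extracts high-use trail
skeletons from the 100-m surface, and turns trail distances into the
binary / exponential-decay covariates used by the selection models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree
from skimage.morphology import skeletonize

from .grid import GridSpec

#: neighborhood radii (m) considered when scaling recreation intensity
RADII = (30.0, 100.0, 500.0, 1000.0)


@dataclass
class IntensitySurface:
    """Point-density raster for one activity type, year and radius.

    Cell value = (number of GPS points within ``radius`` of the cell
    center) / (pi * radius^2 in km^2), i.e. points per km^2.
    """

    values: np.ndarray
    grid: GridSpec
    radius: float
    activity_type: str | None = None
    year: int | None = None

    def sample(self, x, y) -> np.ndarray:
        return self.grid.sample(self.values, x, y)

    def standardized(self) -> np.ndarray:
        from .grid import standardize_field

        return standardize_field(self.values)


def point_density(
    points: np.ndarray,
    radius: float,
    grid: GridSpec,
    activity_type: str | None = None,
    year: int | None = None,
) -> IntensitySurface:
    """Circular-neighborhood point density on a grid.

    ``points`` is an (n, 2) array of x/y in meters.  An empty point set
    yields an all-zero surface.  Neighborhoods extending past the grid
    edge simply count the points that exist (counts stay exact within
    the radius).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    area_km2 = np.pi * radius**2 / 1e6
    if len(points) == 0:
        values = np.zeros(grid.shape)
    else:
        tree = cKDTree(points)
        cx, cy = grid.center_coords()
        counts = tree.query_ball_point(
            np.column_stack([cx, cy]), r=radius, return_length=True
        )
        values = (counts / area_km2).reshape(grid.shape)
    return IntensitySurface(values, grid, radius, activity_type, year)


@dataclass
class TrailSet:
    """Skeletonized high-use trail cells for one activity type.

    ``geoms`` holds the skeleton as line segments between neighboring
    skeleton-cell centers (isolated cells appear as points); an STRtree
    answers nearest-distance queries.  ``empty`` marks the no-trail
    sentinel: distance queries then return NaN and downstream trail
    covariates for the type should be dropped.
    """

    activity_type: str | None
    cell_mask: np.ndarray
    grid: GridSpec
    geoms: list = field(default_factory=list)
    threshold: float = np.nan

    @property
    def empty(self) -> bool:
        return len(self.geoms) == 0

    def __post_init__(self):
        self._tree = STRtree(self.geoms) if self.geoms else None

    def distance(self, x, y) -> np.ndarray:
        """Distance (m) from each point to the nearest trail; NaN if the
        trail set is empty."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if self.empty:
            return np.full(x.shape, np.nan)
        pts = shapely.points(x, y)
        _, dist = self._tree.query_nearest(pts, return_distance=True, all_matches=False)
        return np.asarray(dist, dtype=float)


def _skeleton_geoms(mask: np.ndarray, grid: GridSpec) -> list:
    """Morphological thinning of the trail-cell mask, returned as
    segments joining 8-connected skeleton cell centers."""
    skel = skeletonize(mask)
    ys, xs = np.nonzero(skel)
    if len(xs) == 0:
        return []
    cs = grid.cell_size
    cx = grid.xmin + (xs + 0.5) * cs
    cy = grid.ymin + (ys + 0.5) * cs
    index = {(iy, ix): k for k, (iy, ix) in enumerate(zip(ys, xs))}
    geoms = []
    connected = np.zeros(len(xs), dtype=bool)
    for k, (iy, ix) in enumerate(zip(ys, xs)):
        for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):  # forward half-neighborhood
            j = index.get((iy + dy, ix + dx))
            if j is not None:
                geoms.append(LineString([(cx[k], cy[k]), (cx[j], cy[j])]))
                connected[k] = connected[j] = True
    for k in np.flatnonzero(~connected):
        geoms.append(Point(cx[k], cy[k]))
    return geoms


def extract_trails(
    surface: IntensitySurface,
    percentile: float = 25.0,
    include_zero_cells: bool = False,
) -> TrailSet:
    """Trail features from the high-intensity cells of a 100-m surface.

    The threshold is the given percentile of the surface's cell values
    -- by default over *nonzero* cells only, since with a vast zero
    background the low percentiles of all cells are zero and a strict
    ">" test degenerates.  Trail cells are cells strictly above the
    threshold; their mask is thinned to a centerline skeleton.
    """
    if surface.radius != 100.0:
        warnings.warn(
            f"trail extraction is defined on the 100 m surface, got {surface.radius} m"
        )
    vals = surface.values
    pool = vals[vals > 0] if not include_zero_cells else vals.ravel()
    if pool.size == 0:
        return TrailSet(surface.activity_type, np.zeros(vals.shape, bool), surface.grid, [])
    threshold = float(np.percentile(pool, percentile))
    mask = vals > threshold
    geoms = _skeleton_geoms(mask, surface.grid)
    return TrailSet(surface.activity_type, mask, surface.grid, geoms, threshold)


def distance_to_trail(x, y, trails: TrailSet) -> np.ndarray:
    """Euclidean distance (m) from locations to the nearest trail
    feature; NaN sentinel when the trail set is empty."""
    return trails.distance(x, y)


def trail_covariate(distances, form: str, value: float) -> np.ndarray:
    """Trail-proximity covariate from distances.

    ``form='binary'``: 1 where distance <= ``value`` (threshold in m,
    inclusive), else 0.  ``form='decay'``: exp(-alpha/d) with
    alpha=``value``; the d=0 limit is 0, so the covariate increases from
    0 on a trail toward 1 far away.  NaN distances propagate.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d[~np.isnan(d)] < 0):
        raise ValueError("distances must be >= 0")
    if form == "binary":
        out = np.where(d <= value, 1.0, 0.0)
    elif form == "decay":
        with np.errstate(divide="ignore"):
            out = np.where(d == 0, 0.0, np.exp(-value / d))
    else:
        raise ValueError(f"unknown trail covariate form {form!r}")
    return np.where(np.isnan(d), np.nan, out)


#: candidate trail-covariate forms screened per activity type
BINARY_THRESHOLDS = (250.0, 500.0, 1000.0)
DECAY_ALPHAS = (50.0, 100.0, 250.0, 500.0, 2500.0)


def candidate_trail_forms() -> list[tuple[str, float]]:
    """All 8 candidate forms: 3 binary thresholds + 5 decay constants."""
    return [("binary", t) for t in BINARY_THRESHOLDS] + [
        ("decay", a) for a in DECAY_ALPHAS
    ]


def counter_use_index(hits, days_deployed):
    """Trail-counter use index: season hit count / days deployed (hits/day).

    Accepts scalars or aligned arrays; returns per-counter indices.
    """
    hits = np.asarray(hits, dtype=float)
    days = np.asarray(days_deployed, dtype=float)
    if np.any(days <= 0):
        raise ValueError("days_deployed must be > 0")
    return hits / days


def counter_summary(hits, days_deployed) -> dict:
    """Per-counter indices with mean/SD summary."""
    idx = counter_use_index(hits, days_deployed)
    return {"indices": idx, "mean": float(np.mean(idx)), "sd": float(np.std(idx, ddof=1)) if idx.size > 1 else np.nan}
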