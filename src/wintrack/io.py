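"""Plain-text IO: fix/track CSV, ESRI-ASCII rasters, GeoJSON polygons.

All spatial data are in one projected planar CRS in meters; rasters are
written as ESRI ASCII grids (readable by any GIS) and vector data as
GeoJSON whose coordinates are the same planar meters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .grid import GridSpec


def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    """Write a fix/track table with ISO-8601 timestamps."""
    df = fixes.copy()
    if "timestamp" in df.columns:
        df["timestamp"] = pd.DatetimeIndex(df["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S%z")
    df.to_csv(path, index=False)


def read_fixes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "timestamp" in df.columns:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def write_ascii_grid(values: np.ndarray, grid: GridSpec, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid; rows in the file run north to south."""
    header = (
        f"ncols {grid.nx}\nnrows {grid.ny}\n"
        f"xllcorner {grid.xmin}\nyllcorner {grid.ymin}\n"
        f"cellsize {grid.cell_size}\nNODATA_value {nodata}\n"
    )
    body = np.flipud(np.where(np.isfinite(values), values, nodata))
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    with open(path) as fh:
        head = {}
        for _ in range(6):
            k, v = fh.readline().split()
            head[k.lower()] = float(v)
        vals = np.loadtxt(fh)
    ncols, nrows = int(head["ncols"]), int(head["nrows"])
    cs = head["cellsize"]
    grid = GridSpec(
        head["xllcorner"],
        head["yllcorner"],
        head["xllcorner"] + ncols * cs,
        head["yllcorner"] + nrows * cs,
        cs,
    )
    vals = np.flipud(vals.reshape(nrows, ncols))
    vals[vals == head["nodata_value"]] = np.nan
    return vals, grid


def write_geojson(geoms, path, properties: list[dict] | None = None) -> None:
    """GeoJSON FeatureCollection from shapely geometries (planar meters)."""
    geoms = list(geoms) if not isinstance(geoms, (list, tuple)) else geoms
    props = properties or [{} for _ in geoms]
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": p}
            for g, p in zip(geoms, props)
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path) -> list:
    fc = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in fc["features"]]
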