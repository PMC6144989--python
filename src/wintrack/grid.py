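"""Planar raster grid used throughout the package.

All spatial data live in a single projected planar coordinate system in
meters (no geodesy): analyses are local (home-range scale), so a metric
CRS such as a UTM zone is assumed for real-data ingestion.

A raster is a plain ``numpy`` array of shape ``(ny, nx)`` paired with a
:class:`GridSpec`.  Row ``iy`` covers ``ymin + iy*cell .. ymin + (iy+1)*cell``
(y increases with row index), column ``ix`` likewise in x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned grid of square cells in projected meters."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise ValueError("degenerate extent: max must exceed min in x and y")

    @property
    def nx(self) -> int:
        return int(np.ceil((self.xmax - self.xmin) / self.cell_size))

    @property
    def ny(self) -> int:
        return int(np.ceil((self.ymax - self.ymin) / self.cell_size))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x_centers(self) -> np.ndarray:
        return self.xmin + (np.arange(self.nx) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.ymin + (np.arange(self.ny) + 0.5) * self.cell_size

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays of all cell-center (x, y) coordinates."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return xx.ravel(), yy.ravel()

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; clipped to the grid."""
        ix = np.clip(((np.asarray(x) - self.xmin) / self.cell_size).astype(int), 0, self.nx - 1)
        iy = np.clip(((np.asarray(y) - self.ymin) / self.cell_size).astype(int), 0, self.ny - 1)
        return iy, ix

    def sample(self, values: np.ndarray, x, y) -> np.ndarray:
        """Nearest-cell lookup of raster ``values`` at point coordinates."""
        if values.shape != self.shape:
            raise ValueError(f"raster shape {values.shape} != grid shape {self.shape}")
        iy, ix = self.index_of(x, y)
        return values[iy, ix]

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)

    @property
    def area_km2(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin) / 1e6


def standardize_field(values: np.ndarray) -> np.ndarray:
    """Z-score a raster over all its cells; a constant field maps to zeros."""
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd
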