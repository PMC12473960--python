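"""Local Cartesian analysis grid and the 365-day model calendar.

The study grid is a regular raster in a local equal-area frame measured in
kilometres; cell (iy, ix) has its centre at ``(x0 + (ix+0.5)*cell, y0 +
(iy+0.5)*cell)``.  "longitude"/"latitude" in occurrence tables refer to these
x/y coordinates.  Area shares are cell-count ratios, which is exact on an
equal-area grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Days per calendar month in the 365-day (no-leap) model calendar.
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: Month number (1..12) for each day of a 365-day year.
MONTH_OF_DAY = np.repeat(np.arange(1, 13), MONTH_LENGTHS)

#: Day-of-year (0-based) of each month's middle, used for seasonal profiles.
MONTH_CENTERS = np.cumsum(MONTH_LENGTHS) - MONTH_LENGTHS / 2.0

DAYS_PER_YEAR = 365


def calendar(n_years: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (year, month, doy) arrays for ``n_years`` of 365-day years."""
    doy = np.tile(np.arange(DAYS_PER_YEAR), n_years)
    month = np.tile(MONTH_OF_DAY, n_years)
    year = np.repeat(np.arange(n_years), DAYS_PER_YEAR)
    return year, month, doy


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the regular analysis raster (km units, row-major y/x)."""

    nx: int
    ny: int
    cell_size: float = 1.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell_size,
            self.y0 + self.ny * self.cell_size,
        )

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinate grids, each of shape (ny, nx)."""
        return np.meshgrid(self.x_centers, self.y_centers)

    def cell_center(self, iy, ix) -> tuple[np.ndarray, np.ndarray]:
        iy = np.asarray(iy)
        ix = np.asarray(ix)
        return (
            self.x0 + (ix + 0.5) * self.cell_size,
            self.y0 + (iy + 0.5) * self.cell_size,
        )

    def point_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (iy, ix) indices; points outside get index -1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.x0) / self.cell_size).astype(int)
        iy = np.floor((y - self.y0) / self.cell_size).astype(int)
        inside = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        ix = np.where(inside, ix, -1)
        iy = np.where(inside, iy, -1)
        return iy, ix

    def contains(self, x, y) -> np.ndarray:
        iy, _ = self.point_to_cell(x, y)
        return iy >= 0

    def cell_id(self, iy, ix) -> np.ndarray:
        """Flatten (iy, ix) into a scalar cell identifier."""
        return np.asarray(iy) * self.nx + np.asarray(ix)
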