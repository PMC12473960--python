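"""In-memory container for one ensemble member's daily climate.

A :class:`ClimateCube` holds daily maximum/mean/minimum air temperature and
precipitation on the analysis grid for an integer number of 365-day years.
NetCDF round-tripping goes through :mod:`xarray` (classic format, scipy
backend), with dims (time, y, x) and variables tasmax/tas/tasmin/pr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .grid import DAYS_PER_YEAR, GridSpec, calendar


@dataclass
class ClimateCube:
    """Daily tasmax/tas/tasmin (degC) and pr (mm/day) for one member."""

    member_id: str
    grid: GridSpec
    tasmax: np.ndarray
    tas: np.ndarray
    tasmin: np.ndarray
    pr: np.ndarray
    year: np.ndarray = field(repr=False, default=None)
    month: np.ndarray = field(repr=False, default=None)
    doy: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        ndays = self.tas.shape[0]
        if ndays % DAYS_PER_YEAR != 0:
            raise ValueError("cube must cover whole 365-day years")
        if self.year is None:
            self.year, self.month, self.doy = calendar(ndays // DAYS_PER_YEAR)
        for name in ("tasmax", "tas", "tasmin", "pr"):
            arr = getattr(self, name)
            if arr.shape != (ndays, self.grid.ny, self.grid.nx):
                raise ValueError(f"{name} shape {arr.shape} does not match "
                                 f"calendar/grid")

    @property
    def n_years(self) -> int:
        return self.tas.shape[0] // DAYS_PER_YEAR

    @property
    def n_days(self) -> int:
        return self.tas.shape[0]

    def validate(self) -> None:
        """Check physical invariants (ordering of temperatures, pr >= 0)."""
        if np.any(self.tasmin > self.tas) or np.any(self.tas > self.tasmax):
            raise ValueError("temperature ordering violated "
                             "(need tasmin <= tas <= tasmax)")
        if np.any(self.pr < 0):
            raise ValueError("negative precipitation")

    def to_dataset(self) -> xr.Dataset:
        coords = {
            "time": np.arange(self.n_days, dtype=np.int32),
            "y": self.grid.y_centers,
            "x": self.grid.x_centers,
            "year": ("time", self.year.astype(np.int32)),
            "month": ("time", self.month.astype(np.int32)),
        }
        data = {
            name: (("time", "y", "x"), getattr(self, name))
            for name in ("tasmax", "tas", "tasmin", "pr")
        }
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["member_id"] = self.member_id
        ds.attrs["cell_size"] = self.grid.cell_size
        ds.attrs["x0"] = self.grid.x0
        ds.attrs["y0"] = self.grid.y0
        return ds

    def to_netcdf(self, path) -> None:
        # netCDF3 classic via the scipy backend: portable, no extra deps.
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "ClimateCube":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        grid = GridSpec(
            nx=ds.sizes["x"], ny=ds.sizes["y"],
            cell_size=float(ds.attrs["cell_size"]),
            x0=float(ds.attrs["x0"]), y0=float(ds.attrs["y0"]),
        )
        return cls(
            member_id=str(ds.attrs["member_id"]),
            grid=grid,
            tasmax=ds["tasmax"].values,
            tas=ds["tas"].values,
            tasmin=ds["tasmin"].values,
            pr=ds["pr"].values,
        )
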