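"""Bio-ecological indicators from daily climate, and Rivas-Martinez
thermotype/ombrotype classification.

Indicator conventions
---------------------
* Thermicity index ``It = (T + M + m) * 10`` where T is the annual mean of
  the twelve monthly mean temperatures, and M / m are the mean daily maximum
  and minimum temperatures of the coldest month (the month with the lowest
  monthly mean, ties broken by earliest calendar month), all in degC.
* Annual ombrothermic index ``Io = 10 * Pp / Tp`` where Pp is the total
  precipitation (mm) of months with positive mean temperature and Tp is the
  sum of those months' mean temperatures in tenths of degC (i.e. 10 x degC).
* Continentality ``Ic`` = warmest minus coldest monthly mean temperature.
* ``RR_summer`` = mean annual June-August precipitation total (mm).
* ``TXX_aug`` = mean over years of the annual maximum daily maximum
  temperature of August (degC).
* ``R95PTOT`` = percent of annual precipitation falling on days wetter than
  the baseline-period 95th percentile of wet-day (>= 1 mm) amounts.
* ``TX90P`` = percent of days with tasmax above the baseline-period 90th
  percentile of all daily tasmax (whole-period percentile, no calendar-day
  windowing).
* De Martonne aridity ``DMI = P_annual / (T_annual + 10)``.

It and Io are computed from the period climatology (bioclimatic-normal
practice), not per-year-then-averaged.  Class intervals are lower-inclusive /
upper-exclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimateCube
from .grid import GridSpec

logger = logging.getLogger(__name__)

WET_DAY_MM = 1.0  # ETCCDI wet-day threshold

OUT_OF_TABLE = "out_of_table"

# (label, lower bound inclusive, upper bound exclusive)
THERMOTYPE_CLASSES = [
    ("upper supramediterranean", -150.0, 150.0),
    ("lower supramediterranean", 150.0, 220.0),
    ("upper mesomediterranean", 220.0, 285.0),
    ("lower mesomediterranean", 285.0, 350.0),
    ("upper thermomediterranean", 350.0, 400.0),
    ("lower thermomediterranean", 400.0, 450.0),
    ("upper inframediterranean", 450.0, 515.0),
]

# The arid belt below 1.0 Io adopts the worldwide-classification bounds
# [0.2, 1.0); the hyperhumid belt is closed above at 24.0.
OMBROTYPE_CLASSES = [
    ("arid", 0.2, 1.0),
    ("lower semiarid", 1.0, 1.4),
    ("upper semiarid", 1.4, 2.0),
    ("lower dry", 2.0, 2.7),
    ("upper dry", 2.7, 3.6),
    ("lower subhumid", 3.6, 4.6),
    ("upper subhumid", 4.6, 6.0),
    ("lower humid", 6.0, 8.5),
    ("upper humid", 8.5, 12.0),
    ("hyperhumid", 12.0, 24.0),
]


@dataclass
class MonthlyClimatology:
    """Per-cell monthly means over all years of a period (12, ny, nx)."""

    tas: np.ndarray      # monthly mean temperature, degC
    tasmax: np.ndarray   # monthly mean daily maximum, degC
    tasmin: np.ndarray   # monthly mean daily minimum, degC
    pr_total: np.ndarray  # mean monthly precipitation total, mm
    grid: GridSpec

    def __post_init__(self) -> None:
        for name in ("tas", "tasmax", "tasmin", "pr_total"):
            arr = getattr(self, name)
            if arr.shape != (12, self.grid.ny, self.grid.nx):
                raise ValueError(f"{name} must have shape (12, ny, nx)")


@dataclass
class IndicatorStack:
    """Named per-cell indicator grids for one period/scenario."""

    data: dict[str, np.ndarray]
    grid: GridSpec
    period: str = ""
    scenario: str = "baseline"
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, arr in self.data.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"indicator {name!r} shape mismatch")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.data.keys())

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def __contains__(self, name: str) -> bool:
        return name in self.data

    def subset(self, names) -> "IndicatorStack":
        missing = [n for n in names if n not in self.data]
        if missing:
            raise KeyError(f"indicators not in stack: {missing}")
        return IndicatorStack(
            data={n: self.data[n] for n in names},
            grid=self.grid, period=self.period,
            scenario=self.scenario, members=self.members,
        )

    def to_frame(self) -> pd.DataFrame:
        """Cell-wise table (one row per grid cell, row-major order)."""
        return pd.DataFrame({n: v.ravel() for n, v in self.data.items()})


@dataclass
class ClassMap:
    """Grid of class labels plus the (label, lo, hi) class table."""

    codes: np.ndarray                 # int; -1 = out_of_table
    classes: list[tuple[str, float, float]]
    grid: GridSpec
    indicator: str = ""

    @property
    def labels(self) -> list[str]:
        return [c[0] for c in self.classes]

    def label_grid(self) -> np.ndarray:
        lut = np.array(self.labels + [OUT_OF_TABLE], dtype=object)
        return lut[np.where(self.codes < 0, len(self.labels), self.codes)]


def monthly_climatology(cube: ClimateCube) -> MonthlyClimatology:
    """Monthly means of tas/tasmax/tasmin and mean monthly pr totals."""
    # ClimateCube enforces whole 365-day years on construction.
    ny, nx = cube.grid.shape
    tas = np.empty((12, ny, nx))
    tasmax = np.empty((12, ny, nx))
    tasmin = np.empty((12, ny, nx))
    pr_total = np.empty((12, ny, nx))
    for m in range(12):
        sel = cube.month == (m + 1)
        tas[m] = cube.tas[sel].mean(axis=0, dtype=np.float64)
        tasmax[m] = cube.tasmax[sel].mean(axis=0, dtype=np.float64)
        tasmin[m] = cube.tasmin[sel].mean(axis=0, dtype=np.float64)
        pr_total[m] = (cube.pr[sel].sum(axis=0, dtype=np.float64)
                       / cube.n_years)
    return MonthlyClimatology(tas=tas, tasmax=tasmax, tasmin=tasmin,
                              pr_total=pr_total, grid=cube.grid)


def thermicity_index(clim: MonthlyClimatology) -> np.ndarray:
    """It = (T + M + m) x 10; larger values mean milder winters."""
    t_annual = clim.tas.mean(axis=0)
    coldest = clim.tas.argmin(axis=0)  # argmin takes the earliest tie
    m_max = np.take_along_axis(clim.tasmax, coldest[None], axis=0)[0]
    m_min = np.take_along_axis(clim.tasmin, coldest[None], axis=0)[0]
    return (t_annual + m_max + m_min) * 10.0


def ombrothermic_index(clim: MonthlyClimatology) -> np.ndarray:
    """Io = 10 * Pp / Tp over positive-temperature months; NaN where no
    month has positive mean temperature."""
    positive = clim.tas > 0.0
    pp = np.where(positive, clim.pr_total, 0.0).sum(axis=0)
    tp = np.where(positive, 10.0 * clim.tas, 0.0).sum(axis=0)
    io = np.full(tp.shape, np.nan)
    ok = tp > 0.0
    io[ok] = 10.0 * pp[ok] / tp[ok]
    if not ok.all():
        logger.warning(
            "ombrothermic index undefined in %d cells "
            "(no month with positive mean temperature)", (~ok).sum()
        )
    return io


def continentality_index(clim: MonthlyClimatology) -> np.ndarray:
    """Ic = warmest minus coldest monthly mean temperature (degC range)."""
    return clim.tas.max(axis=0) - clim.tas.min(axis=0)


def de_martonne(clim: MonthlyClimatology) -> np.ndarray:
    """DMI = P_annual / (T_annual + 10); NaN where T_annual <= -10."""
    p_annual = clim.pr_total.sum(axis=0)
    t_annual = clim.tas.mean(axis=0)
    dmi = np.full(t_annual.shape, np.nan)
    ok = t_annual > -10.0
    dmi[ok] = p_annual[ok] / (t_annual[ok] + 10.0)
    if not ok.all():
        logger.warning("De Martonne index undefined in %d cells",
                       (~ok).sum())
    return dmi


def rr_summer(cube: ClimateCube) -> np.ndarray:
    """Mean annual June-August precipitation total (mm)."""
    summer = np.isin(cube.month, (6, 7, 8))
    return (cube.pr[summer].sum(axis=0, dtype=np.float64) / cube.n_years)


def txx_aug(cube: ClimateCube) -> np.ndarray:
    """Mean over years of the August maximum of daily maximum temperature."""
    august = cube.month == 8
    ny, nx = cube.grid.shape
    per_year = cube.tasmax[august].reshape(cube.n_years, -1, ny, nx)
    return per_year.max(axis=1).mean(axis=0, dtype=np.float64)


def wet_day_q95(reference: ClimateCube) -> np.ndarray:
    """Per-cell 95th percentile of wet-day (>= 1 mm) amounts in the
    reference period; NaN where the reference has no wet days."""
    pr = reference.pr
    ndays = pr.shape[0]
    flat = np.sort(pr.reshape(ndays, -1), axis=0)  # ascending, dry first
    n_wet = (flat >= WET_DAY_MM).sum(axis=0)
    q95 = np.full(flat.shape[1], np.nan)
    ok = n_wet > 0
    # Linear interpolation at rank 0.95*(n_wet-1) within the wet tail.
    pos = 0.95 * (n_wet[ok] - 1)
    lo = np.floor(pos).astype(int)
    hi = np.ceil(pos).astype(int)
    start = ndays - n_wet[ok]
    cols = np.nonzero(ok)[0]
    v_lo = flat[start + lo, cols]
    v_hi = flat[start + hi, cols]
    q95[ok] = v_lo + (pos - lo) * (v_hi - v_lo)
    if not ok.all():
        logger.warning("R95PTOT reference has no wet days in %d cells",
                       (~ok).sum())
    return q95.reshape(reference.grid.shape)


def r95ptot(cube: ClimateCube, reference: ClimateCube) -> np.ndarray:
    """Percent of precipitation from days above the reference wet-day 95th
    percentile, averaged over years."""
    q95 = wet_day_q95(reference)
    ny, nx = cube.grid.shape
    pr = cube.pr.reshape(cube.n_years, -1, ny, nx)
    extreme = pr * (pr > q95[None, None])
    num = extreme.sum(axis=1, dtype=np.float64)
    den = pr.sum(axis=1, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den > 0, 100.0 * num / den, np.nan)
    return ratio.mean(axis=0)


def tx90p(cube: ClimateCube, reference: ClimateCube) -> np.ndarray:
    """Percent of days with tasmax above the reference 90th percentile."""
    t90 = np.quantile(reference.tasmax.astype(np.float64), 0.9, axis=0)
    return 100.0 * (cube.tasmax > t90).mean(axis=0, dtype=np.float64)


def compute_indicators(
    cube: ClimateCube,
    reference: ClimateCube | None = None,
    scenario: str = "baseline",
    period: str = "",
) -> IndicatorStack:
    """The 14 bioclimatic candidate indicators for one member.

    ``reference`` supplies the baseline percentiles for R95PTOT/TX90P and
    defaults to the cube itself (appropriate for the baseline period).
    """
    if reference is None:
        reference = cube
    clim = monthly_climatology(cube)
    coldest = clim.tas.argmin(axis=0)
    warmest = clim.tas.argmax(axis=0)
    data = {
        "It": thermicity_index(clim),
        "Io": ombrothermic_index(clim),
        "Ic": continentality_index(clim),
        "DMI": de_martonne(clim),
        "RR_summer": rr_summer(cube),
        "TXX_aug": txx_aug(cube),
        "R95PTOT": r95ptot(cube, reference),
        "TX90P": tx90p(cube, reference),
        "tas_annual": clim.tas.mean(axis=0),
        "pr_annual": clim.pr_total.sum(axis=0),
        "tasmin_coldest": np.take_along_axis(
            clim.tasmin, coldest[None], axis=0)[0],
        "tasmax_warmest": np.take_along_axis(
            clim.tasmax, warmest[None], axis=0)[0],
        "tasmax_annual": clim.tasmax.mean(axis=0),
        "wet_days": (cube.pr >= WET_DAY_MM).sum(axis=0).astype(float)
        / cube.n_years,
    }
    return IndicatorStack(data=data, grid=cube.grid, period=period,
                          scenario=scenario, members=(cube.member_id,))


def slope_from_elevation(elevation):
    """Terrain slope magnitude (m per km of horizontal distance)."""
    step = elevation.grid.cell_size  # km
    gy, gx = np.gradient(elevation.values, step)
    return np.hypot(gx, gy)


def add_topography(stack: IndicatorStack, elevation) -> IndicatorStack:
    """Append the two topographic candidates (DTM, Slope) to a stack."""
    data = dict(stack.data)
    data["DTM"] = elevation.values.copy()
    data["Slope"] = slope_from_elevation(elevation)
    return IndicatorStack(data=data, grid=stack.grid, period=stack.period,
                          scenario=stack.scenario, members=stack.members)


def ensemble_mean(stacks: list[IndicatorStack]) -> IndicatorStack:
    """Unweighted cell-wise mean across members, indicator by indicator."""
    if not stacks:
        raise ValueError("no stacks to average")
    names = stacks[0].names
    for s in stacks[1:]:
        if s.names != names:
            raise ValueError("indicator registries differ between members")
        if s.grid != stacks[0].grid:
            raise ValueError("grids differ between members")
    data = {
        n: np.mean([s[n] for s in stacks], axis=0) for n in names
    }
    members = tuple(m for s in stacks for m in s.members)
    return IndicatorStack(data=data, grid=stacks[0].grid,
                          period=stacks[0].period,
                          scenario=stacks[0].scenario, members=members)


def _classify(values: np.ndarray, classes, grid, indicator) -> ClassMap:
    codes = np.full(values.shape, -1, dtype=int)
    for i, (_, lo, hi) in enumerate(classes):
        codes[(values >= lo) & (values < hi)] = i
    # The topmost class is closed above (e.g. hyperhumid includes 24.0 only
    # by convention of the printed table upper bound being exclusive; the
    # suitability scale handles its own closure separately).
    codes[~np.isfinite(values)] = -1
    return ClassMap(codes=codes, classes=list(classes), grid=grid,
                    indicator=indicator)


def classify_thermotype(it: np.ndarray, grid: GridSpec) -> ClassMap:
    """Map thermicity values onto the thermotype horizons."""
    return _classify(np.asarray(it, dtype=float), THERMOTYPE_CLASSES,
                     grid, "It")


def classify_ombrotype(io: np.ndarray, grid: GridSpec) -> ClassMap:
    """Map ombrothermic values onto the ombrotype horizons."""
    return _classify(np.asarray(io, dtype=float), OMBROTYPE_CLASSES,
                     grid, "Io")


def area_percentages(class_map: ClassMap) -> pd.Series:
    """Percent of grid cells per class label (including out_of_table);
    sums to 100."""
    labels = class_map.label_grid().ravel()
    counts = pd.Series(labels).value_counts()
    order = class_map.labels + [OUT_OF_TABLE]
    counts = counts.reindex(order, fill_value=0)
    return 100.0 * counts / counts.sum()


def occurrence_class_distribution(
    class_map: ClassMap,
    occurrences: pd.DataFrame,
) -> pd.Series:
    """Percent of occurrence points per class; points outside the grid are
    excluded (and logged)."""
    if len(occurrences) == 0:
        raise ValueError("empty occurrence set")
    iy, ix = class_map.grid.point_to_cell(
        occurrences["longitude"].to_numpy(),
        occurrences["latitude"].to_numpy(),
    )
    inside = iy >= 0
    if not inside.all():
        logger.warning("%d occurrence points fall outside the grid and "
                       "were excluded", (~inside).sum())
    if not inside.any():
        raise ValueError("no occurrence points inside the grid")
    codes = class_map.codes[iy[inside], ix[inside]]
    lut = np.array(class_map.labels + [OUT_OF_TABLE], dtype=object)
    labels = lut[np.where(codes < 0, len(class_map.labels), codes)]
    counts = pd.Series(labels).value_counts()
    order = class_map.labels + [OUT_OF_TABLE]
    counts = counts.reindex(order, fill_value=0)
    return 100.0 * counts / counts.sum()
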