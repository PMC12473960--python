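"""Synthetic study system: elevation, multi-member daily climate, a known
true suitability surface, occurrence records, and protected-area polygons.

Everything is a pure, deterministic function of a :class:`SyntheticConfig`.
The generator emulates the structure of the real study inputs: a multi-member
daily climate ensemble over a 20-year window with elevation-driven temperature
and precipitation gradients, a "future" scenario that warms all temperatures
additively and scales precipitation multiplicatively, presence records sampled
from a known logistic suitability surface (with deliberately injected dirty
records so cleaning is exercised), and rectangular protected-area polygons in
two designation groups.

Random streams are keyed by (seed, purpose tag, member), never by scenario,
so baseline and perturbed climates share their weather noise exactly; the
scenario enters only as a post-hoc additive temperature offset and a
multiplicative precipitation factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .areas import DESIGNATIONS, ProtectedArea
from .climate import ClimateCube
from .config import SyntheticConfig
from .grid import DAYS_PER_YEAR, MONTH_CENTERS, GridSpec, calendar

logger = logging.getLogger(__name__)

SCENARIOS = ("baseline", "future")

# Stream tags: distinct sub-seeds per generator purpose.
_TAG_ELEVATION = 101
_TAG_GEOGRAPHY = 151
_TAG_MEMBER_OFFSETS = 199
_TAG_WEATHER = 211
_TAG_OCCURRENCES = 307
_TAG_AREAS = 401

# Relative monthly temperature anomaly: coldest in January, warmest in
# August (a skewed annual cycle, as in maritime mid-latitude climates).
_MONTHLY_TAS_SHAPE = np.array(
    [-1.00, -0.95, -0.60, -0.20, 0.25, 0.65, 0.92, 1.00,
     0.70, 0.25, -0.35, -0.80]
)


@dataclass(frozen=True)
class ElevationRaster:
    """Terrain height (m) on the analysis grid."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("elevation shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("elevation must be finite everywhere")


@dataclass(frozen=True)
class SyntheticOccurrenceReport:
    """Exact bookkeeping of planted clean and dirty records."""

    n_valid: int
    n_duplicates: int
    n_out_of_domain: int
    n_missing_coords: int

    @property
    def n_total(self) -> int:
        return (self.n_valid + self.n_duplicates + self.n_out_of_domain
                + self.n_missing_coords)


def _seasonal_profile(doy: np.ndarray, amplitude: float) -> np.ndarray:
    """Periodic interpolation of the monthly temperature shape to days."""
    centers = np.concatenate(
        [MONTH_CENTERS - DAYS_PER_YEAR, MONTH_CENTERS,
         MONTH_CENTERS + DAYS_PER_YEAR]
    )
    values = np.tile(_MONTHLY_TAS_SHAPE, 3)
    return amplitude * np.interp(doy, centers, values)


def _winter_weight(doy: np.ndarray) -> np.ndarray:
    """1 near mid-January, 0 near mid-July (Mediterranean wet season)."""
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (doy - 15.0) / DAYS_PER_YEAR))


def generate_elevation(config: SyntheticConfig) -> ElevationRaster:
    """Base plane plus 2-4 seeded Gaussian ridges; non-negative everywhere."""
    grid = config.grid
    rng = np.random.default_rng([config.seed, _TAG_ELEVATION])
    xx, yy = grid.center_mesh()
    xmin, ymin, xmax, ymax = grid.extent
    span = min(xmax - xmin, ymax - ymin)

    # Gentle tilted plane; its relief scales with the ridge amplitude so a
    # zero-amplitude configuration degenerates to a constant plane.
    angle = rng.uniform(0.0, 2.0 * np.pi)
    tilt = 0.1 * config.ridge_amplitude_m
    plane = tilt * ((xx - xmin) * np.cos(angle)
                    + (yy - ymin) * np.sin(angle)) / max(span, 1e-12)

    n_ridges = int(rng.integers(2, 5))
    elev = np.full(grid.shape, config.base_elevation_m, dtype=float) + plane
    for _ in range(n_ridges):
        cx = rng.uniform(xmin, xmax)
        cy = rng.uniform(ymin, ymax)
        width = rng.uniform(0.08, 0.25) * span
        amp = config.ridge_amplitude_m * rng.uniform(0.5, 1.0)
        elev += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                             / (2.0 * width ** 2))
    return ElevationRaster(values=np.maximum(elev, 0.0), grid=grid)


def geography_fields(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Smooth, standardised spatial fields that shape the local climate
    independently of elevation.

    ``continentality`` widens the seasonal temperature cycle (colder
    winters, hotter summers); ``moisture_winter`` and ``moisture_summer``
    scale the wet-season and dry-season precipitation separately.  Their
    mutual independence is what keeps the winter-cold, summer-heat, annual-
    moisture and summer-rain indicators from collapsing onto a single
    elevation gradient, mirroring the correlation structure under which
    all four survive collinearity screening in real mountain climates.

    A small domain holds only a few tens of independent patches at this
    correlation length, so independently drawn fields can align by chance;
    each field is therefore orthogonalised (over cells) against elevation
    and the previously generated fields, which plants the independence
    exactly for every seed.  Linear combinations of smooth fields remain
    smooth.
    """
    from scipy.ndimage import gaussian_filter

    grid = config.grid
    rng = np.random.default_rng([config.seed, _TAG_GEOGRAPHY])
    sigma = 0.10 * min(grid.nx, grid.ny)

    elev = generate_elevation(config).values.ravel()
    basis = [np.ones(grid.n_cells)]
    if elev.std() > 0:
        basis.append((elev - elev.mean()) / elev.std())

    fields: dict[str, np.ndarray] = {}
    for name in ("continentality", "moisture_winter", "moisture_summer"):
        raw = rng.standard_normal(grid.shape)
        smooth = gaussian_filter(raw, sigma=sigma, mode="reflect").ravel()
        for b in basis:
            smooth = smooth - (smooth @ b) / (b @ b) * b
        std = smooth.std()
        field = smooth / (std if std > 0 else 1.0)
        basis.append(field)
        fields[name] = field.reshape(grid.shape)
    return fields


def member_offsets(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-member additive temperature offsets (degC) and multiplicative
    precipitation factors, drawn once from a seeded stream."""
    rng = np.random.default_rng([config.seed, _TAG_MEMBER_OFFSETS])
    t_offsets = rng.normal(0.0, 0.6, config.n_members)
    p_factors = np.exp(rng.normal(0.0, 0.08, config.n_members))
    return t_offsets, p_factors


def generate_member_climate(
    config: SyntheticConfig,
    elevation: ElevationRaster,
    member: int,
    scenario: str = "baseline",
) -> ClimateCube:
    """Daily climate for one ensemble member under one scenario.

    The seasonal temperature cycle is coldest in January and warmest in
    August; temperature falls with elevation at the configured lapse rate;
    precipitation follows a winter-wet/summer-dry cycle with an orographic
    enhancement factor.  ``scenario="future"`` adds ``scenario_delta_t`` to
    all temperatures and multiplies precipitation by
    ``1 + scenario_delta_p``; weather noise is shared with the baseline.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"expected one of {SCENARIOS}")
    if elevation.grid != config.grid:
        raise ValueError("elevation grid does not match configuration")
    if not (0 <= member < config.n_members):
        raise ValueError(f"member {member} out of range")

    grid = config.grid
    ndays = config.n_years * DAYS_PER_YEAR
    _, _, doy = calendar(config.n_years)
    elev = elevation.values.astype(np.float32)

    t_offsets, p_factors = member_offsets(config)
    rng = np.random.default_rng([config.seed, _TAG_WEATHER, member])

    # Fixed draw order, independent of scenario, so noise is shared.
    synoptic = rng.normal(0.0, 1.5, (ndays, 1, 1)).astype(np.float32)
    local = rng.standard_normal((ndays, grid.ny, grid.nx),
                                dtype=np.float32) * np.float32(0.8)
    u_wet = rng.random((ndays, grid.ny, grid.nx), dtype=np.float32)
    u_amt = rng.random((ndays, grid.ny, grid.nx), dtype=np.float32)

    geography = geography_fields(config)
    cont = geography["continentality"].astype(np.float32)

    anomaly = _seasonal_profile(doy, config.seasonal_amplitude_c)
    # Continentality widens the seasonal cycle per cell.
    tas = (np.float32(config.sea_level_tas_c)
           + anomaly.astype(np.float32)[:, None, None]
           * (np.float32(1.0) + np.float32(0.35) * cont)[None, :, :]
           - np.float32(config.lapse_rate_c_per_m) * elev[None, :, :]
           + np.float32(t_offsets[member]) + synoptic + local)
    del local, synoptic

    # Diurnal half-range: wider in the dry summer season.
    winter = _winter_weight(doy).astype(np.float32)
    half_range = (np.float32(4.0)
                  + np.float32(2.0) * (1.0 - winter))[:, None, None]

    # Precipitation: daily wet probability and mean rate follow the winter
    # weight; amounts are exponential; orography and the season-specific
    # moisture fields enhance totals.
    wet_prob = (0.25 + 0.40 * winter)[:, None, None].astype(np.float32)
    mean_rate = (0.6 + 3.6 * winter)[:, None, None].astype(np.float32)
    moist = np.exp(
        winter[:, None, None]
        * geography["moisture_winter"].astype(np.float32)[None, :, :] * 0.8
        + (1.0 - winter)[:, None, None]
        * geography["moisture_summer"].astype(np.float32)[None, :, :] * 0.8
    ).astype(np.float32)
    # Orographic enhancement acts on stratiform winter rain far more than
    # on convective summer showers.
    orographic = (np.float32(1.0)
                  + winter[:, None, None]
                  * (elev / 2500.0)[None, :, :].astype(np.float32))
    amounts = -(mean_rate / wet_prob) * np.log(
        np.maximum(u_amt, np.float32(1e-12)))
    pr = (np.where(u_wet < wet_prob, amounts, np.float32(0.0))
          * orographic * moist)
    del u_wet, u_amt, amounts, moist, orographic

    if scenario == "future":
        tas = tas + np.float32(config.scenario_delta_t)
        pr = pr * np.float32(1.0 + config.scenario_delta_p)

    cube = ClimateCube(
        member_id=f"member-{member:02d}",
        grid=grid,
        tasmax=tas + half_range,
        tas=tas,
        tasmin=tas - half_range,
        pr=pr,
    )
    return cube


def generate_climate(
    config: SyntheticConfig,
    elevation: ElevationRaster,
    scenario: str = "baseline",
) -> list[ClimateCube]:
    """All ensemble members' cubes (memory-hungry at full scale; prefer
    :func:`generate_member_climate` in streaming pipelines)."""
    return [
        generate_member_climate(config, elevation, m, scenario)
        for m in range(config.n_members)
    ]


def true_suitability(stack, config: SyntheticConfig) -> np.ndarray:
    """Known ground-truth habitat suitability in [0, 1].

    ``logistic(intercept + sum_k coef_k * z_k)`` over the per-stack
    standardised indicators named in ``config.true_coefficients``.
    """
    from scipy.special import expit

    eta = np.full(stack.grid.shape, float(config.true_intercept))
    for name, coef in config.true_coefficients.items():
        if name not in stack.names:
            raise KeyError(
                f"true-suitability indicator {name!r} missing from stack "
                f"(available: {sorted(stack.names)})"
            )
        values = stack[name]
        mean = np.nanmean(values)
        std = np.nanstd(values)
        z = (values - mean) / std if std > 0 else np.zeros_like(values)
        eta = eta + coef * z
    return expit(eta)


def sample_occurrences(
    truth: np.ndarray,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, SyntheticOccurrenceReport]:
    """Draw presence records proportional to the true suitability.

    Each draw selects a cell with probability proportional to ``truth`` and
    places the point at the cell centre plus sub-cell jitter.  Dirty records
    are then injected -- exact coordinate duplicates, points outside the
    domain, and records with missing coordinates -- and counted in the
    report so cleaning tests have exact expectations.
    """
    grid = config.grid
    weights = np.nan_to_num(np.asarray(truth, dtype=float), nan=0.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("true suitability is zero everywhere; "
                         "cannot normalise sampling weights")

    rng = np.random.default_rng([config.seed, _TAG_OCCURRENCES])
    n = config.n_presence_draws
    cells = rng.choice(grid.n_cells, size=n, p=weights / total)
    iy, ix = np.divmod(cells, grid.nx)
    cx, cy = grid.cell_center(iy, ix)
    jitter = rng.uniform(-0.5, 0.5, (2, n)) * grid.cell_size

    records = pd.DataFrame(
        {
            "species": "Gentiana pneumonanthe",
            "longitude": cx + jitter[0],
            "latitude": cy + jitter[1],
            "source_id": [f"occ-{i:05d}" for i in range(n)],
        }
    )

    # Exact duplicates of existing points (new ids, same coordinates).
    n_dup = int(round(config.duplicate_fraction * n))
    dup_rows = records.iloc[rng.integers(0, n, n_dup)].copy()
    dup_rows["source_id"] = [f"dup-{i:05d}" for i in range(n_dup)]

    # Out-of-domain points ("middle of the ocean" analogue).
    xmin, ymin, xmax, ymax = grid.extent
    n_out = config.n_out_of_domain
    out_rows = pd.DataFrame(
        {
            "species": "Gentiana pneumonanthe",
            "longitude": xmax + (1.0 + np.arange(n_out)) * 10 * grid.cell_size,
            "latitude": np.full(n_out, ymin - 10 * grid.cell_size),
            "source_id": [f"ood-{i:05d}" for i in range(n_out)],
        }
    )

    n_miss = config.n_missing_coords
    miss_rows = pd.DataFrame(
        {
            "species": "Gentiana pneumonanthe",
            "longitude": np.full(n_miss, np.nan),
            "latitude": np.full(n_miss, np.nan),
            "source_id": [f"nan-{i:05d}" for i in range(n_miss)],
        }
    )

    raw = pd.concat([records, dup_rows, out_rows, miss_rows],
                    ignore_index=True)
    report = SyntheticOccurrenceReport(
        n_valid=n,
        n_duplicates=n_dup,
        n_out_of_domain=n_out,
        n_missing_coords=n_miss,
    )
    return raw, report


def generate_protected_areas(config: SyntheticConfig) -> list[ProtectedArea]:
    """Seeded axis-aligned rectangles in two designation groups, all
    strictly inside the grid footprint."""
    grid = config.grid
    xmin, ymin, xmax, ymax = grid.extent
    rng = np.random.default_rng([config.seed, _TAG_AREAS])
    areas: list[ProtectedArea] = []
    for designation in DESIGNATIONS:
        n_rect = int(rng.integers(1, 6))
        for k in range(n_rect):
            w = rng.uniform(0.08, 0.30) * (xmax - xmin)
            h = rng.uniform(0.08, 0.30) * (ymax - ymin)
            x = rng.uniform(xmin, xmax - w)
            y = rng.uniform(ymin, ymax - h)
            areas.append(
                ProtectedArea(
                    designation=designation,
                    name=f"{designation}-{k:02d}",
                    geometry=box(x, y, x + w, y + h),
                )
            )
    return areas
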