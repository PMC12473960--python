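"""Configuration of the synthetic study system.

The defaults define the desk-scale study conditions: a 100 x 100 km grid at
1 km resolution, a nine-member climate ensemble over a 20-year window, and a
perturbed-climate scenario that warms every day by +4 degC and dries
precipitation by 30% -- a late-century high-forcing analogue.  The true
suitability surface is a logistic function of the standardised indicators
in which the ombrothermic (moisture) index dominates positively and August
extreme heat contributes negatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .grid import GridSpec


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


def _default_coefficients() -> Mapping[str, float]:
    return MappingProxyType({"Io": 2.5, "TXX_aug": -1.5})


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of one synthetic study; all outputs are a pure
    function of this object."""

    grid_nx: int = 100
    grid_ny: int = 100
    cell_size_km: float = 1.0
    n_members: int = 9
    n_years: int = 20
    seed: int = 42
    scenario_delta_t: float = 4.0      # additive warming, degC
    scenario_delta_p: float = -0.3     # fractional precipitation change
    true_coefficients: Mapping[str, float] = field(
        default_factory=_default_coefficients
    )
    true_intercept: float = -1.0
    n_presence_draws: int = 1000

    # Elevation field: base plane plus seeded Gaussian ridges.
    base_elevation_m: float = 100.0
    ridge_amplitude_m: float = 1200.0

    # Atmosphere: lapse rate and seasonal temperature/precipitation shape.
    lapse_rate_c_per_m: float = 0.0065
    sea_level_tas_c: float = 14.0
    seasonal_amplitude_c: float = 9.0

    # Dirty-record injection, so occurrence cleaning is exercised with
    # exact expectations.
    duplicate_fraction: float = 0.05
    n_out_of_domain: int = 3
    n_missing_coords: int = 2

    def __post_init__(self) -> None:
        if self.grid_nx <= 0 or self.grid_ny <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.grid_nx * self.grid_ny < 100:
            raise ConfigurationError("grid must have at least 100 cells")
        if self.cell_size_km <= 0:
            raise ConfigurationError("cell size must be positive")
        if self.n_members < 1:
            raise ConfigurationError("need at least one ensemble member")
        if self.n_years < 1:
            raise ConfigurationError("need at least one year")
        if not (-1.0 < self.scenario_delta_p <= 1.0):
            raise ConfigurationError(
                "scenario_delta_p must lie in (-1, 1]"
            )
        if self.n_presence_draws < 1:
            raise ConfigurationError("n_presence_draws must be >= 1")
        if not (0.0 <= self.duplicate_fraction < 1.0):
            raise ConfigurationError("duplicate_fraction must be in [0, 1)")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(nx=self.grid_nx, ny=self.grid_ny,
                        cell_size=self.cell_size_km)
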