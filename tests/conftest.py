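"""Shared fixtures: a small but complete synthetic study, and helpers to
construct hand-made climate cubes for indicator oracles."""

from __future__ import annotations

import numpy as np
import pytest

from gentiana_sdm.climate import ClimateCube
from gentiana_sdm.config import SyntheticConfig
from gentiana_sdm.grid import GridSpec
from gentiana_sdm.pipeline import run_pipeline


def build_cube(
    rng: np.random.Generator | None = None,
    ny: int = 5,
    nx: int = 5,
    n_years: int = 2,
    tas=None,
    tasmax=None,
    tasmin=None,
    pr=None,
    member_id: str = "test",
) -> ClimateCube:
    """A ClimateCube from explicit arrays, or random float64 fields."""
    ndays = n_years * 365
    shape = (ndays, ny, nx)
    if tas is None:
        tas = rng.uniform(-5.0, 25.0, shape)
    tas = np.broadcast_to(np.asarray(tas, dtype=float), shape).copy()
    if tasmax is None:
        tasmax = tas + (rng.uniform(0.0, 8.0, shape) if rng is not None
                        else 5.0)
    if tasmin is None:
        tasmin = tas - (rng.uniform(0.0, 8.0, shape) if rng is not None
                        else 5.0)
    if pr is None:
        if rng is not None:
            pr = np.maximum(rng.normal(1.0, 4.0, shape), 0.0)
        else:
            pr = np.ones(shape)
    tasmax = np.broadcast_to(np.asarray(tasmax, dtype=float), shape).copy()
    tasmin = np.broadcast_to(np.asarray(tasmin, dtype=float), shape).copy()
    pr = np.broadcast_to(np.asarray(pr, dtype=float), shape).copy()
    return ClimateCube(member_id=member_id, grid=GridSpec(nx=nx, ny=ny),
                       tasmax=tasmax, tas=tas, tasmin=tasmin, pr=pr)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(grid_nx=40, grid_ny=40, n_members=3, n_years=4,
                           n_presence_draws=400, seed=7)


@pytest.fixture(scope="session")
def small_result(small_config):
    """One complete small pipeline run shared across module tests."""
    return run_pipeline(small_config, ratios=(1, 3), cv_repeats=3)
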