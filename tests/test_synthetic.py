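"""Determinism, scenario arithmetic, and sampling behaviour of the
synthetic study-system generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from gentiana_sdm.config import ConfigurationError, SyntheticConfig
from gentiana_sdm.grid import GridSpec
from gentiana_sdm.bioclim import IndicatorStack
from gentiana_sdm.synthetic import (generate_elevation,
                                    generate_member_climate,
                                    generate_protected_areas,
                                    sample_occurrences, true_suitability)


class TestConfig:
    def test_rejects_degenerate_grids(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(grid_nx=0, grid_ny=10)
        with pytest.raises(ConfigurationError):
            SyntheticConfig(grid_nx=5, grid_ny=5)  # fewer than 100 cells

    def test_rejects_total_drying(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(scenario_delta_p=-1.0)


class TestElevation:
    def test_same_seed_is_bit_identical(self):
        cfg = SyntheticConfig(grid_nx=20, grid_ny=20, seed=1)
        a = generate_elevation(cfg).values
        b = generate_elevation(cfg).values
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_elevation(SyntheticConfig(grid_nx=20, grid_ny=20,
                                               seed=1)).values
        b = generate_elevation(SyntheticConfig(grid_nx=20, grid_ny=20,
                                               seed=2)).values
        assert np.any(a != b)

    def test_zero_amplitude_gives_constant_plane(self):
        cfg = SyntheticConfig(grid_nx=10, grid_ny=10,
                              ridge_amplitude_m=0.0)
        elev = generate_elevation(cfg).values
        assert np.allclose(elev, cfg.base_elevation_m)

    def test_non_negative_everywhere(self):
        elev = generate_elevation(SyntheticConfig(grid_nx=30, grid_ny=30,
                                                  seed=3)).values
        assert np.all(elev >= 0) and np.all(np.isfinite(elev))


@pytest.fixture(scope="module")
def cfg():
    return SyntheticConfig(grid_nx=12, grid_ny=12, n_members=3,
                           n_years=2, seed=5, scenario_delta_t=4.0,
                           scenario_delta_p=-0.3)


@pytest.fixture(scope="module")
def elevation(cfg):
    return generate_elevation(cfg)


class TestClimate:
    def test_warming_shifts_all_temperatures_additively(self, cfg,
                                                        elevation):
        base = generate_member_climate(cfg, elevation, 0, "baseline")
        future = generate_member_climate(cfg, elevation, 0, "future")
        # Shared weather noise: the shift is exact, day by day, cell-wise.
        np.testing.assert_allclose(future.tas - base.tas, 4.0, atol=1e-3)
        august = base.month == 8
        assert future.tasmax[august].mean() == pytest.approx(
            base.tasmax[august].mean() + 4.0, abs=1e-4)

    def test_drying_scales_precipitation_multiplicatively(self, cfg,
                                                          elevation):
        base = generate_member_climate(cfg, elevation, 0, "baseline")
        future = generate_member_climate(cfg, elevation, 0, "future")
        np.testing.assert_allclose(
            future.pr.sum(axis=0), 0.7 * base.pr.sum(axis=0), rtol=1e-4)

    def test_members_share_shape_but_differ(self, cfg, elevation):
        cubes = [generate_member_climate(cfg, elevation, m)
                 for m in range(cfg.n_members)]
        assert len({c.tas.shape for c in cubes}) == 1
        means = [float(c.tas.mean()) for c in cubes]
        assert len(set(np.round(means, 6))) == cfg.n_members

    def test_physical_invariants_hold(self, cfg, elevation):
        cube = generate_member_climate(cfg, elevation, 1)
        cube.validate()  # tasmin <= tas <= tasmax, pr >= 0

    def test_unknown_scenario_rejected(self, cfg, elevation):
        with pytest.raises(ValueError, match="scenario"):
            generate_member_climate(cfg, elevation, 0, "rcp85")

    def test_scenario_monotonicity_propagates_to_indicators(self, cfg,
                                                            elevation):
        from gentiana_sdm import bioclim

        base = generate_member_climate(cfg, elevation, 0, "baseline")
        future = generate_member_climate(cfg, elevation, 0, "future")
        s0 = bioclim.compute_indicators(base)
        s1 = bioclim.compute_indicators(future, reference=base)
        # Warming strictly raises August heat and the thermicity index;
        # drying strictly lowers summer precipitation, grid-mean-wise.
        assert s1["TXX_aug"].mean() > s0["TXX_aug"].mean()
        assert s1["It"].mean() > s0["It"].mean()
        assert s1["RR_summer"].mean() < s0["RR_summer"].mean()


class TestTrueSuitability:
    def _stack(self, values: dict):
        grid = GridSpec(nx=10, ny=10)
        return IndicatorStack(
            data={k: np.asarray(v, dtype=float) for k, v in values.items()},
            grid=grid)

    def test_zero_coefficients_give_uniform_half(self):
        rng = np.random.default_rng(0)
        stack = self._stack({"Io": rng.normal(size=(10, 10))})
        cfg = SyntheticConfig(true_coefficients={"Io": 0.0},
                              true_intercept=0.0)
        np.testing.assert_allclose(true_suitability(stack, cfg), 0.5)

    def test_large_intercept_saturates_towards_one(self):
        rng = np.random.default_rng(0)
        stack = self._stack({"Io": rng.normal(size=(10, 10))})
        previous = -np.inf
        for intercept in (0.0, 2.0, 5.0, 20.0):
            cfg = SyntheticConfig(true_coefficients={"Io": 1.0},
                                  true_intercept=intercept)
            value = true_suitability(stack, cfg).min()
            assert value > previous
            previous = value
        assert previous > 0.999

    def test_matches_hand_computed_logistic_at_one_cell(self):
        values = np.arange(100, dtype=float).reshape(10, 10)
        stack = self._stack({"Io": values})
        cfg = SyntheticConfig(true_coefficients={"Io": 2.0},
                              true_intercept=-0.5)
        z = (values[3, 4] - values.mean()) / values.std()
        expected = 1.0 / (1.0 + np.exp(-(-0.5 + 2.0 * z)))
        assert true_suitability(stack, cfg)[3, 4] == pytest.approx(
            expected, abs=1e-12)

    def test_missing_indicator_is_named_in_error(self):
        stack = self._stack({"Io": np.zeros((10, 10))})
        cfg = SyntheticConfig(true_coefficients={"TXX_aug": 1.0})
        with pytest.raises(KeyError, match="TXX_aug"):
            true_suitability(stack, cfg)


class TestOccurrenceSampling:
    def test_degenerate_truth_puts_all_points_in_one_cell(self):
        cfg = SyntheticConfig(grid_nx=10, grid_ny=10,
                              n_presence_draws=50, n_out_of_domain=0,
                              n_missing_coords=0, duplicate_fraction=0.0)
        truth = np.zeros((10, 10))
        truth[4, 7] = 1.0
        occ, _ = sample_occurrences(truth, cfg)
        iy, ix = cfg.grid.point_to_cell(occ["longitude"], occ["latitude"])
        assert np.all(iy == 4) and np.all(ix == 7)

    def test_presence_fraction_follows_two_level_truth(self):
        cfg = SyntheticConfig(grid_nx=20, grid_ny=20,
                              n_presence_draws=10_000, seed=11,
                              n_out_of_domain=0, n_missing_coords=0,
                              duplicate_fraction=0.0)
        truth = np.full((20, 20), 0.1)
        truth[:, 10:] = 0.9
        occ, _ = sample_occurrences(truth, cfg)
        frac_high = (occ["longitude"] > 10.0).mean()
        assert frac_high == pytest.approx(0.9, abs=0.02)

    def test_repeated_run_is_identical(self):
        cfg = SyntheticConfig(grid_nx=10, grid_ny=10, n_presence_draws=200,
                              seed=3)
        truth = np.random.default_rng(0).uniform(size=(10, 10))
        a, _ = sample_occurrences(truth, cfg)
        b, _ = sample_occurrences(truth, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_truth_is_an_error(self):
        cfg = SyntheticConfig(grid_nx=10, grid_ny=10)
        with pytest.raises(ValueError, match="normalise"):
            sample_occurrences(np.zeros((10, 10)), cfg)

    def test_density_rank_correlates_with_truth(self):
        cfg = SyntheticConfig(grid_nx=20, grid_ny=20,
                              n_presence_draws=5000, seed=13,
                              n_out_of_domain=0, n_missing_coords=0,
                              duplicate_fraction=0.0)
        truth = np.random.default_rng(1).uniform(size=(20, 20))
        occ, _ = sample_occurrences(truth, cfg)
        iy, ix = cfg.grid.point_to_cell(occ["longitude"], occ["latitude"])
        counts = np.zeros((20, 20))
        np.add.at(counts, (iy, ix), 1)
        rho = spearmanr(counts.ravel(), truth.ravel()).statistic
        assert rho > 0.5


class TestProtectedAreas:
    def test_polygons_inside_grid_and_deterministic(self):
        cfg = SyntheticConfig(grid_nx=30, grid_ny=30, seed=9)
        areas = generate_protected_areas(cfg)
        xmin, ymin, xmax, ymax = cfg.grid.extent
        assert {a.designation for a in areas} == {"natura2000", "ramsar"}
        total = 0.0
        for a in areas:
            bx0, by0, bx1, by1 = a.geometry.bounds
            assert bx0 >= xmin and by0 >= ymin
            assert bx1 <= xmax and by1 <= ymax
            total += a.geometry.area
        assert total < (xmax - xmin) * (ymax - ymin)
        again = generate_protected_areas(cfg)
        assert all(a.geometry.equals(b.geometry)
                   for a, b in zip(areas, again))
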