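"""Indicator computations against independent brute-force oracles, and
the thermotype/ombrotype classification tables.

The oracles below recompute every indicator with plain Python loops over
cells, months and years, sharing no code with the package implementation.
"""

import numpy as np
import pandas as pd
import pytest

from conftest import build_cube
from gentiana_sdm import bioclim
from gentiana_sdm.grid import MONTH_OF_DAY, GridSpec

# ---------------------------------------------------------------- oracles


def oracle_monthly(cube):
    """(tas, tasmax, tasmin means; mean monthly pr totals) by loops."""
    ny, nx = cube.grid.shape
    out = {k: np.zeros((12, ny, nx)) for k in
           ("tas", "tasmax", "tasmin", "pr_total")}
    for m in range(1, 13):
        sel = [i for i in range(cube.n_days) if cube.month[i] == m]
        for iy in range(ny):
            for ix in range(nx):
                out["tas"][m - 1, iy, ix] = np.mean(
                    [cube.tas[i, iy, ix] for i in sel])
                out["tasmax"][m - 1, iy, ix] = np.mean(
                    [cube.tasmax[i, iy, ix] for i in sel])
                out["tasmin"][m - 1, iy, ix] = np.mean(
                    [cube.tasmin[i, iy, ix] for i in sel])
                out["pr_total"][m - 1, iy, ix] = (
                    sum(cube.pr[i, iy, ix] for i in sel) / cube.n_years)
    return out


def oracle_it(cube):
    mon = oracle_monthly(cube)
    ny, nx = cube.grid.shape
    it = np.zeros((ny, nx))
    for iy in range(ny):
        for ix in range(nx):
            tas12 = mon["tas"][:, iy, ix]
            cold = int(np.argmin(tas12))
            it[iy, ix] = (tas12.mean() + mon["tasmax"][cold, iy, ix]
                          + mon["tasmin"][cold, iy, ix]) * 10.0
    return it


def oracle_io(cube):
    mon = oracle_monthly(cube)
    ny, nx = cube.grid.shape
    io = np.full((ny, nx), np.nan)
    for iy in range(ny):
        for ix in range(nx):
            pp = tp = 0.0
            for m in range(12):
                if mon["tas"][m, iy, ix] > 0:
                    pp += mon["pr_total"][m, iy, ix]
                    tp += 10.0 * mon["tas"][m, iy, ix]
            if tp > 0:
                io[iy, ix] = 10.0 * pp / tp
    return io


def oracle_rr_summer(cube):
    ny, nx = cube.grid.shape
    out = np.zeros((ny, nx))
    for iy in range(ny):
        for ix in range(nx):
            total = sum(cube.pr[i, iy, ix] for i in range(cube.n_days)
                        if cube.month[i] in (6, 7, 8))
            out[iy, ix] = total / cube.n_years
    return out


def oracle_txx_aug(cube):
    ny, nx = cube.grid.shape
    out = np.zeros((ny, nx))
    for iy in range(ny):
        for ix in range(nx):
            maxima = []
            for y in range(cube.n_years):
                days = [i for i in range(y * 365, (y + 1) * 365)
                        if cube.month[i] == 8]
                maxima.append(max(cube.tasmax[i, iy, ix] for i in days))
            out[iy, ix] = np.mean(maxima)
    return out


def oracle_r95ptot(cube, reference):
    ny, nx = cube.grid.shape
    out = np.full((ny, nx), np.nan)
    for iy in range(ny):
        for ix in range(nx):
            wet = [reference.pr[i, iy, ix]
                   for i in range(reference.n_days)
                   if reference.pr[i, iy, ix] >= 1.0]
            if not wet:
                continue
            q95 = np.quantile(wet, 0.95)
            ratios = []
            for y in range(cube.n_years):
                days = range(y * 365, (y + 1) * 365)
                total = sum(cube.pr[i, iy, ix] for i in days)
                extreme = sum(cube.pr[i, iy, ix] for i in days
                              if cube.pr[i, iy, ix] > q95)
                ratios.append(100.0 * extreme / total if total > 0
                              else np.nan)
            out[iy, ix] = np.mean(ratios)
    return out


def oracle_tx90p(cube, reference):
    ny, nx = cube.grid.shape
    out = np.zeros((ny, nx))
    for iy in range(ny):
        for ix in range(nx):
            t90 = np.quantile(reference.tasmax[:, iy, ix], 0.9)
            above = sum(cube.tasmax[i, iy, ix] > t90
                        for i in range(cube.n_days))
            out[iy, ix] = 100.0 * above / cube.n_days
    return out


def oracle_dmi(cube):
    mon = oracle_monthly(cube)
    p_annual = mon["pr_total"].sum(axis=0)
    t_annual = mon["tas"].mean(axis=0)
    return np.where(t_annual > -10.0, p_annual / (t_annual + 10.0), np.nan)


def oracle_ic(cube):
    mon = oracle_monthly(cube)
    return mon["tas"].max(axis=0) - mon["tas"].min(axis=0)


# ----------------------------------------------------------------- tests


@pytest.fixture(scope="module")
def random_cube():
    return build_cube(np.random.default_rng(42), ny=5, nx=5, n_years=2)


class TestClimatology:
    def test_constant_temperature_reproduced(self):
        cube = build_cube(ny=3, nx=3, n_years=1, tas=10.0)
        clim = bioclim.monthly_climatology(cube)
        np.testing.assert_allclose(clim.tas, 10.0)

    def test_uniform_rain_gives_month_length_totals(self):
        cube = build_cube(ny=3, nx=3, n_years=1, tas=10.0, pr=1.0)
        clim = bioclim.monthly_climatology(cube)
        assert clim.pr_total[0, 0, 0] == pytest.approx(31.0)  # January
        assert clim.pr_total[1, 0, 0] == pytest.approx(28.0)  # February

    def test_two_year_average_halves_the_offset(self):
        ndays = 2 * 365
        tas = np.zeros((ndays, 2, 2))
        tas[365:] = 2.0
        cube = build_cube(ny=2, nx=2, n_years=2, tas=tas)
        clim = bioclim.monthly_climatology(cube)
        np.testing.assert_allclose(clim.tas, 1.0)

    def test_partial_year_is_rejected(self):
        from gentiana_sdm.climate import ClimateCube
        from gentiana_sdm.grid import GridSpec
        arr = np.zeros((100, 2, 2))
        with pytest.raises(ValueError, match="365"):
            ClimateCube(member_id="x", grid=GridSpec(nx=2, ny=2),
                        tasmax=arr, tas=arr, tasmin=arr, pr=arr)


INDICATOR_ORACLES = [
    ("It", bioclim.thermicity_index, oracle_it, "clim"),
    ("Io", bioclim.ombrothermic_index, oracle_io, "clim"),
    ("Ic", bioclim.continentality_index, oracle_ic, "clim"),
    ("DMI", bioclim.de_martonne, oracle_dmi, "clim"),
    ("RR_summer", bioclim.rr_summer, oracle_rr_summer, "cube"),
    ("TXX_aug", bioclim.txx_aug, oracle_txx_aug, "cube"),
]


class TestIndicatorOracles:
    @pytest.mark.parametrize("name,func,oracle,arg",
                             INDICATOR_ORACLES,
                             ids=[x[0] for x in INDICATOR_ORACLES])
    def test_matches_brute_force(self, random_cube, name, func, oracle,
                                 arg):
        if arg == "clim":
            got = func(bioclim.monthly_climatology(random_cube))
        else:
            got = func(random_cube)
        np.testing.assert_allclose(got, oracle(random_cube), atol=1e-9)

    def test_r95ptot_matches_brute_force(self, random_cube):
        got = bioclim.r95ptot(random_cube, random_cube)
        np.testing.assert_allclose(got, oracle_r95ptot(random_cube,
                                                       random_cube),
                                   atol=1e-9)

    def test_tx90p_matches_brute_force(self, random_cube):
        got = bioclim.tx90p(random_cube, random_cube)
        np.testing.assert_allclose(got, oracle_tx90p(random_cube,
                                                     random_cube),
                                   atol=1e-9)

    def test_warming_shifts_thermicity_by_thirty_delta(self, random_cube):
        delta = 1.7
        warmed = build_cube(
            ny=5, nx=5, n_years=2,
            tas=random_cube.tas + delta,
            tasmax=random_cube.tasmax + delta,
            tasmin=random_cube.tasmin + delta,
            pr=random_cube.pr,
        )
        it0 = bioclim.thermicity_index(
            bioclim.monthly_climatology(random_cube))
        it1 = bioclim.thermicity_index(
            bioclim.monthly_climatology(warmed))
        np.testing.assert_allclose(it1 - it0, 30.0 * delta, atol=1e-9)
        np.testing.assert_allclose(bioclim.rr_summer(warmed),
                                   bioclim.rr_summer(random_cube),
                                   atol=1e-12)


class TestIndicatorProperties:
    def test_it_known_value_and_class(self):
        # T=10, M=8, m=0 -> It=180, in the lower supramediterranean belt.
        ndays = 365
        tas = np.full((ndays, 2, 2), 10.0)
        tasmax = tas + np.where(MONTH_OF_DAY == 1, -2.0, 5.0)[:, None,
                                                              None]
        cube = build_cube(ny=2, nx=2, n_years=1, tas=tas, tasmax=tasmax,
                          tasmin=tas - 10.0, pr=1.0)
        clim = bioclim.monthly_climatology(cube)
        # All monthly means tie at 10 degC, so the earliest month
        # (January) provides M = 8 and m = 0.
        it = bioclim.thermicity_index(clim)
        np.testing.assert_allclose(it, (10.0 + 8.0 + 0.0) * 10.0)
        cmap = bioclim.classify_thermotype(it, cube.grid)
        assert np.all(cmap.label_grid() == "lower supramediterranean")

    def test_io_uniform_case_and_linearity(self):
        # 12 months at 10 degC with ~100 mm each: Io = 10, upper humid.
        pr = (100.0 / np.repeat(
            np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]),
            [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]))
        cube = build_cube(ny=2, nx=2, n_years=1, tas=10.0,
                          pr=pr[:, None, None])
        clim = bioclim.monthly_climatology(cube)
        io = bioclim.ombrothermic_index(clim)
        np.testing.assert_allclose(io, 10.0, atol=1e-9)
        omap = bioclim.classify_ombrotype(io, cube.grid)
        assert np.all(omap.label_grid() == "upper humid")
        half = build_cube(ny=2, nx=2, n_years=1, tas=10.0,
                          pr=0.5 * pr[:, None, None])
        io_half = bioclim.ombrothermic_index(
            bioclim.monthly_climatology(half))
        np.testing.assert_allclose(io_half, 0.5 * io, atol=1e-9)

    def test_ic_shift_invariance_and_constant_zero(self):
        cube = build_cube(ny=2, nx=2, n_years=1, tas=7.0)
        clim = bioclim.monthly_climatology(cube)
        np.testing.assert_allclose(
            bioclim.continentality_index(clim), 0.0, atol=1e-12)
        rng = np.random.default_rng(1)
        cube2 = build_cube(rng, ny=3, nx=3, n_years=1)
        shifted = build_cube(ny=3, nx=3, n_years=1, tas=cube2.tas + 5.0,
                             tasmax=cube2.tasmax + 5.0,
                             tasmin=cube2.tasmin + 5.0, pr=cube2.pr)
        np.testing.assert_allclose(
            bioclim.continentality_index(
                bioclim.monthly_climatology(cube2)),
            bioclim.continentality_index(
                bioclim.monthly_climatology(shifted)),
            atol=1e-9)

    def test_rr_summer_day_count(self):
        cube = build_cube(ny=2, nx=2, n_years=1, tas=10.0, pr=1.0)
        np.testing.assert_allclose(bioclim.rr_summer(cube), 92.0)

    def test_txx_aug_single_spike_average(self):
        ndays = 20 * 365
        tasmax = np.full((ndays, 1, 1), 30.0)
        # August 15 of year 0: day index 212 + 14.
        tasmax[226, 0, 0] = 47.0
        cube = build_cube(ny=1, nx=1, n_years=20, tas=tasmax - 5.0,
                          tasmax=tasmax, tasmin=tasmax - 10.0, pr=0.0)
        assert cube.month[226] == 8
        np.testing.assert_allclose(bioclim.txx_aug(cube),
                                   (47.0 + 19 * 30.0) / 20.0)

    def test_r95ptot_zero_for_constant_rain_and_bounded(self, random_cube):
        cube = build_cube(ny=2, nx=2, n_years=1, tas=10.0, pr=2.0)
        np.testing.assert_allclose(bioclim.r95ptot(cube, cube), 0.0)
        vals = bioclim.r95ptot(random_cube, random_cube)
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 100.0

    def test_tx90p_shifted_cube_saturates(self, random_cube):
        hot = build_cube(ny=5, nx=5, n_years=2,
                         tas=random_cube.tas + 50.0,
                         tasmax=random_cube.tasmax + 50.0,
                         tasmin=random_cube.tasmin + 50.0,
                         pr=random_cube.pr)
        np.testing.assert_allclose(bioclim.tx90p(hot, random_cube), 100.0)

    def test_de_martonne_known_value(self):
        # P = 500 mm/yr at T = 15 degC -> DMI = 20.
        pr = np.full(365, 500.0 / 365.0)
        cube = build_cube(ny=2, nx=2, n_years=1, tas=15.0,
                          pr=pr[:, None, None])
        clim = bioclim.monthly_climatology(cube)
        np.testing.assert_allclose(bioclim.de_martonne(clim), 20.0,
                                   atol=1e-9)


class TestEnsembleMean:
    def _stack(self, grid, **data):
        return bioclim.IndicatorStack(
            data={k: np.asarray(v, dtype=float) for k, v in data.items()},
            grid=grid)

    def test_identical_members_preserved(self):
        grid = GridSpec(nx=4, ny=4)
        s = self._stack(grid, It=np.ones((4, 4)))
        out = bioclim.ensemble_mean([s, s, s])
        np.testing.assert_allclose(out["It"], 1.0)

    def test_opposite_members_cancel(self):
        grid = GridSpec(nx=4, ny=4)
        v = np.random.default_rng(2).normal(size=(4, 4))
        out = bioclim.ensemble_mean(
            [self._stack(grid, It=v), self._stack(grid, It=-v)])
        np.testing.assert_allclose(out["It"], 0.0, atol=1e-15)

    def test_matches_mean_oracle_and_permutation_invariant(self):
        grid = GridSpec(nx=4, ny=4)
        rng = np.random.default_rng(3)
        stacks = [self._stack(grid, It=rng.normal(size=(4, 4)))
                  for _ in range(9)]
        out = bioclim.ensemble_mean(stacks)
        expect = np.mean([s["It"] for s in stacks], axis=0)
        np.testing.assert_allclose(out["It"], expect)
        out2 = bioclim.ensemble_mean(stacks[::-1])
        np.testing.assert_allclose(out["It"], out2["It"])

    def test_mismatched_registries_rejected(self):
        grid = GridSpec(nx=4, ny=4)
        with pytest.raises(ValueError, match="registries"):
            bioclim.ensemble_mean([
                self._stack(grid, It=np.ones((4, 4))),
                self._stack(grid, Io=np.ones((4, 4))),
            ])


class TestClassification:
    def test_thermotype_boundary_probes(self):
        grid = GridSpec(nx=9, ny=1)
        probes = np.array([[-150.0, 150.0, 220.0, 285.0, 300.0, 350.0,
                            400.0, 450.0, 600.0]])
        labels = bioclim.classify_thermotype(probes, grid).label_grid()[0]
        assert list(labels) == [
            "upper supramediterranean", "lower supramediterranean",
            "upper mesomediterranean", "lower mesomediterranean",
            "lower mesomediterranean", "upper thermomediterranean",
            "lower thermomediterranean", "upper inframediterranean",
            "out_of_table",
        ]

    def test_ombrotype_boundary_probes(self):
        grid = GridSpec(nx=7, ny=1)
        probes = np.array([[1.0, 2.0, 2.5, 3.6, 6.0, 12.0, 13.0]])
        labels = bioclim.classify_ombrotype(probes, grid).label_grid()[0]
        assert list(labels) == [
            "lower semiarid", "lower dry", "lower dry", "lower subhumid",
            "lower humid", "hyperhumid", "hyperhumid",
        ]

    def test_classification_is_total_on_finite_inputs(self):
        grid = GridSpec(nx=50, ny=20)
        values = np.random.default_rng(4).uniform(-500, 1000, (20, 50))
        cmap = bioclim.classify_thermotype(values, grid)
        labels = cmap.label_grid()
        assert labels.shape == values.shape
        # Every in-range value has a class; out-of-range -> out_of_table.
        in_range = (values >= -150.0) & (values < 515.0)
        assert np.all((labels != "out_of_table") == in_range)

    def test_area_percentages_sum_to_hundred(self):
        grid = GridSpec(nx=10, ny=10)
        values = np.full((10, 10), 100.0)
        values[:5] = 200.0  # both in supramediterranean belts
        pct = bioclim.area_percentages(
            bioclim.classify_thermotype(values, grid))
        assert pct.sum() == pytest.approx(100.0)
        assert pct["upper supramediterranean"] == pytest.approx(50.0)
        assert pct["lower supramediterranean"] == pytest.approx(50.0)

    def test_occurrence_distribution_counts_and_guards(self):
        grid = GridSpec(nx=10, ny=10)
        values = np.full((10, 10), 100.0)
        cmap = bioclim.classify_thermotype(values, grid)
        occ = pd.DataFrame({"longitude": [0.5, 1.5, 50.0],
                            "latitude": [0.5, 1.5, 0.5]})
        pct = bioclim.occurrence_class_distribution(cmap, occ)
        assert pct["upper supramediterranean"] == pytest.approx(100.0)
        with pytest.raises(ValueError, match="empty"):
            bioclim.occurrence_class_distribution(cmap, occ.iloc[:0])
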