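"""Response screening, dummy-variable models, bootstrap comparison, SEA."""

import numpy as np
import pytest
import scipy.stats

from defolyr.climate import (
    DefoliationDummy,
    bootstrap_r2_compare,
    fit_models,
    friedman_test,
    monthly_design,
    month_variable_names,
    response_screen,
    sea,
)
from defolyr.series import IndexBasis, IndexSeries
from defolyr.simulate import simulate_climate


@pytest.fixture(scope="module")
def climate():
    return simulate_climate(90, seed=1, start_year=1920)


def _chron_from(climate, years, build, noise_sd, seed):
    rng = np.random.default_rng(seed)
    design = monthly_design(climate, years)
    vals = build(design) + rng.normal(0, noise_sd, len(design))
    return IndexSeries(int(design.index[0]), vals, IndexBasis.DOUBLE_DETREND)


class TestMonthlyDesign:
    def test_42_variables_prev_jan_to_current_sep(self, climate):
        design = monthly_design(climate, range(1921, 2010))
        assert list(design.columns) == month_variable_names()
        assert len(design.columns) == 42

    def test_previous_year_alignment(self, climate):
        design = monthly_design(climate, [1950])
        jan_prev = climate.query("year == 1949 and month == 1")[
            "temperature"
        ].iloc[0]
        assert design.loc[1950, "Tjan"] == pytest.approx(jan_prev)


class TestResponseScreen:
    def test_known_driver_detected(self, climate):
        years = list(range(1921, 2001))

        def build(design):
            p_may = design["PMAY"].to_numpy()
            z = (p_may - p_may.mean()) / p_may.std(ddof=1)
            return 1.0 + 0.655 * 0.1 * z  # ~30% variance share at noise 0.1

        chron = _chron_from(climate, years, build, noise_sd=0.1, seed=2)
        significant, table = response_screen(chron, climate, n_boot=300, seed=3)
        assert "PMAY" in significant
        others = [v for v in significant if v != "PMAY"]
        assert len(others) <= 0.10 * 41

    def test_white_noise_no_systematic_excess(self, climate):
        counts = []
        for seed in range(6):
            chron = _chron_from(
                climate, range(1921, 2001), lambda d: np.ones(len(d)),
                noise_sd=0.1, seed=seed,
            )
            sig, _ = response_screen(chron, climate, n_boot=200, seed=seed)
            counts.append(len(sig))
        assert np.mean(counts) <= 0.05 * 42 * 2

    def test_short_overlap_rejected(self, climate):
        chron = IndexSeries(1950, np.ones(10), IndexBasis.DOUBLE_DETREND)
        with pytest.raises(ValueError, match="30 years"):
            response_screen(chron, climate)


class TestFitModels:
    def _simulated(self, climate, b=-0.19, seed=0, events=(1950, 1975, 1990)):
        years = list(range(1921, 2001))
        dummy = DefoliationDummy(list(events))
        rng = np.random.default_rng(seed)
        design = monthly_design(climate, years)
        p_may = design["PMAY"].to_numpy()
        t_jul = design["TJUL"].to_numpy()
        o = dummy.indicator(design.index)
        vals = (
            1.0
            + 0.0017 * (p_may - p_may.mean())
            - 0.019 * (t_jul - t_jul.mean())
            + b * o
            + rng.normal(0, 0.1, len(design))
        )
        chron = IndexSeries(int(design.index[0]), vals, IndexBasis.DOUBLE_DETREND)
        return chron, dummy

    def test_dummy_coefficient_recovered(self, climate):
        chron, dummy = self._simulated(climate, b=-0.19, seed=1)
        fit2, fit3 = fit_models(chron, climate, ["PMAY", "TJUL"], dummy)
        lo, hi = fit3.dummy_ci
        assert lo <= -0.19 <= hi
        assert fit3.r2adj >= fit2.r2adj

    def test_all_zero_dummy_reduces_to_weather_model(self, climate):
        chron, _ = self._simulated(climate, b=0.0, seed=2, events=())
        dummy = DefoliationDummy([])
        fit2, fit3 = fit_models(chron, climate, ["PMAY", "TJUL"], dummy,
                                stepwise=False)
        assert fit3.dummy_coefficient == pytest.approx(0.0)
        assert [n for n, _ in fit3.predictors] == [n for n, _ in fit2.predictors]
        for (n2, c2), (n3, c3) in zip(fit2.predictors, fit3.predictors):
            assert c2 == pytest.approx(c3)

    def test_irrelevant_predictor_eliminated_by_aic(self):
        # an exactly irrelevant month survives backward AIC elimination
        # only when its chance chi-square exceeds ~2, i.e. ~17% of the time
        removed = 0
        n_seeds = 100
        for seed in range(n_seeds):
            clim = simulate_climate(90, seed=100 + seed, start_year=1920)
            chron, dummy = self._simulated(clim, b=-0.19, seed=seed)
            _, fit3 = fit_models(chron, clim, ["PMAY", "TJUL", "Pfeb"], dummy)
            if "Pfeb" not in [n for n, _ in fit3.predictors]:
                removed += 1
        assert removed >= 0.8 * n_seeds


class TestFriedman:
    def test_matches_scipy_for_three_samples(self):
        rng = np.random.default_rng(0)
        a, b, c = rng.normal(0, 1, (3, 40))
        b += 0.5
        stat, p = friedman_test(a, b, c)
        ref_stat, ref_p = scipy.stats.friedmanchisquare(a, b, c)
        assert stat == pytest.approx(ref_stat)
        assert p == pytest.approx(ref_p)

    def test_two_sample_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 60)
        _, p = friedman_test(a, a + 1.0)
        assert p < 1e-6

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            friedman_test([1, 2, 3])


class TestBootstrapCompare:
    def test_true_dummy_effect_highly_significant(self, climate):
        fit = TestFitModels()
        chron, dummy = fit._simulated(climate, b=-0.19, seed=3)
        out = bootstrap_r2_compare(chron, climate, ["PMAY", "TJUL"], dummy,
                                   n_boot=100, seed=0)
        assert out["friedman_p"] < 0.001
        assert np.mean(out["r2adj_dummy"] - out["r2adj_weather"]) > 0

    def test_single_bootstrap_rejected(self, climate):
        fit = TestFitModels()
        chron, dummy = fit._simulated(climate, seed=4)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_r2_compare(chron, climate, ["PMAY"], dummy, n_boot=1)


class TestSea:
    def test_injected_departures_flagged_at_exact_lags(self):
        rng = np.random.default_rng(5)
        n = 100
        vals = 1.0 + rng.normal(0, 0.05, n)
        events = [1925, 1940, 1955, 1970, 1985]
        for e in events:
            for lag in (1, 2):
                vals[e + lag - 1910] -= 0.3
        chron = IndexSeries(1910, vals, IndexBasis.DOUBLE_DETREND)
        out = sea(chron, events, n_draws=500, seed=0)
        sig = set(out.loc[out["significant"], "lag"])
        assert {1, 2} <= sig
        assert out.loc[out["lag"].isin([1, 2]), "mean_departure"].max() < -0.2
        # negative departures nowhere else
        other = out[~out["lag"].isin([1, 2])]
        assert (other["mean_departure"] > -0.1).all()

    def test_too_few_events_rejected(self):
        chron = IndexSeries(1910, np.ones(50), IndexBasis.DOUBLE_DETREND)
        with pytest.raises(ValueError):
            sea(chron, [1920, 1930])
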