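"""Standardisation, screening and chronology-confidence statistics."""

import numpy as np
import pytest

from defolyr.chronology import (
    baillie_pilcher_index,
    double_detrend,
    eps_snr,
    leave_one_out_screen,
    reliable_span,
    site_chronology,
    spline_detrend,
)
from defolyr.series import IndexSeries, SiteCollection
from conftest import make_tree


class TestBailliePilcher:
    def test_constant_series_gives_100(self):
        out = baillie_pilcher_index([2.0] * 6)
        np.testing.assert_allclose(out.values, 100.0)

    def test_spike_hand_arithmetic(self):
        # window at the spike: [1,1,2,1,1], mean 1.2 -> 100*2/1.2
        out = baillie_pilcher_index([1, 1, 1, 2, 1, 1, 1])
        assert out.values[3] == pytest.approx(100 * 2 / 1.2, rel=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.5, 2.0, 40)
        a = baillie_pilcher_index(w).values
        b = baillie_pilcher_index(10 * w).values
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_zero_window_flagged_undefined(self):
        out = baillie_pilcher_index([0, 0, 0, 0, 0, 1, 1, 1])
        assert np.isnan(out.values[0])


class TestSplineDetrend:
    def test_linear_trend_mean_index_near_one(self):
        w = np.linspace(2.0, 0.5, 80)
        out = spline_detrend(w)
        assert abs(np.nanmean(out.values) - 1.0) < 0.01

    def test_constant_series_all_ones(self):
        out = spline_detrend(np.full(50, 1.3))
        np.testing.assert_allclose(out.values, 1.0, atol=1e-6)

    def test_high_frequency_oscillation_preserved(self):
        t = np.arange(100)
        w = 1.0 + 0.2 * np.sin(2 * np.pi * t / 8)
        out = spline_detrend(w)  # stiffness 67 years >> 8-year period
        assert np.nanmax(out.values) >= 1.15
        assert np.nanmin(out.values) <= 0.85

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(0.5, 2.0, 60)
        a = spline_detrend(w).values
        b = spline_detrend(1000 * w).values
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestDoubleDetrend:
    def test_pure_negative_exponential_flattens(self):
        t = np.arange(60, dtype=float)
        w = 1.8 * np.exp(-0.05 * t) + 0.4
        out = double_detrend(w)
        np.testing.assert_allclose(out.values, 1.0, atol=0.02)

    def test_constant_series(self):
        out = double_detrend(np.full(40, 0.9))
        np.testing.assert_allclose(out.values, 1.0, atol=1e-6)

    def test_mean_near_one_for_random_positive_series(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            w = rng.uniform(0.3, 2.5, 50)
            out = double_detrend(w)
            assert abs(np.nanmean(out.values) - 1.0) < 0.05


class TestSiteChronology:
    def test_identical_inputs_identity(self):
        s = IndexSeries(1990, np.linspace(0.8, 1.2, 20))
        out = site_chronology([s, s, s])
        np.testing.assert_allclose(out.values, s.values)

    def test_mean_of_two(self):
        a = IndexSeries(1990, np.full(10, 0.8))
        b = IndexSeries(1990, np.full(10, 1.2))
        np.testing.assert_allclose(site_chronology([a, b]).values, 1.0)

    def test_leave_one_out_bound(self):
        # dropping one of n equal-weight series moves the mean by at most
        # (max deviation)/(n-1)
        rng = np.random.default_rng(8)
        series = [IndexSeries(1990, rng.uniform(0.7, 1.3, 30)) for _ in range(6)]
        full = site_chronology(series).values
        for i in range(6):
            rest = site_chronology(series[:i] + series[i + 1 :]).values
            dev = np.abs(series[i].values - full)
            assert np.all(np.abs(rest - full) <= dev / 5 + 1e-12)


class TestEpsSnr:
    def test_identical_series_eps_one(self):
        s = IndexSeries(1990, np.random.default_rng(0).uniform(0.5, 1.5, 30))
        stats = eps_snr([s, s, s])
        assert stats.eps == pytest.approx(1.0)
        assert np.isinf(stats.snr)

    def test_closed_form_n20_rbar_half(self):
        # construct 20 series with known pairwise structure via common signal
        # and verify the closed form eps = n*rbar/(n*rbar + 1 - rbar) directly
        rng = np.random.default_rng(10)
        common = rng.normal(0, 1, 500)
        series = [
            IndexSeries(1900, common + rng.normal(0, 1, 500)) for _ in range(20)
        ]
        stats = eps_snr(series)
        rbar = stats.rbar
        assert abs(rbar - 0.5) < 0.05  # common share 50% by construction
        expected_eps = 20 * rbar / (20 * rbar + 1 - rbar)
        assert stats.eps == pytest.approx(expected_eps, rel=1e-12)
        assert stats.snr == pytest.approx(20 * rbar / (1 - rbar), rel=1e-12)

    def test_eps_increasing_in_n(self):
        for rbar in (0.2, 0.5, 0.8):
            eps = [n * rbar / (n * rbar + 1 - rbar) for n in range(2, 30)]
            assert all(b > a for a, b in zip(eps, eps[1:]))

    def test_negative_rbar_reported_zero(self):
        a = IndexSeries(1990, np.sin(np.arange(30.0)))
        b = IndexSeries(1990, -np.sin(np.arange(30.0)))
        stats = eps_snr([a, b])
        assert stats.eps == 0.0 and stats.snr == 0.0


class TestReliableSpan:
    def test_identical_series_full_span(self):
        s = IndexSeries(1900, np.random.default_rng(1).uniform(0.5, 1.5, 80))
        assert reliable_span([s, s, s]) == (1900, 1979)

    def test_signal_onset_detected_within_window_step(self):
        rng = np.random.default_rng(12)
        n, onset = 100, 50  # common signal only from index 50
        common = rng.normal(0, 1, n)
        series = []
        for _ in range(8):
            v = rng.normal(0, 1, n)
            v[onset:] += 4 * common[onset:]
            series.append(IndexSeries(1900, v))
        span = reliable_span(series)
        assert span is not None
        assert abs(span[0] - (1900 + onset)) <= 10  # one window step
        assert span[1] == 1999

    def test_eps_min_zero_full_span(self):
        rng = np.random.default_rng(3)
        series = [IndexSeries(1900, rng.normal(1, 0.1, 40)) for _ in range(5)]
        assert reliable_span(series, eps_min=0.0) == (1900, 1939)


class TestLeaveOneOutScreen:
    def _collection(self, vectors, first=1950):
        trees = [
            make_tree(f"T{i}", first, 0.7 * np.asarray(v), 0.3 * np.asarray(v))
            for i, v in enumerate(vectors)
        ]
        return SiteCollection(site_id="s", trees=trees)

    def test_identical_series_all_retained(self):
        v = np.random.default_rng(0).uniform(0.5, 2, 50)
        col = self._collection([v] * 5)
        retained, rejected, r = leave_one_out_screen(col)
        assert rejected == []
        assert all(val == pytest.approx(1.0) for val in r.values())

    def test_independent_noise_series_rejected(self):
        rng = np.random.default_rng(42)
        n = 80
        common = rng.normal(0, 1, n)
        # 4 correlated series: common variance share 0.7
        good = [
            1.0 + 0.2 * (np.sqrt(0.7) * common + np.sqrt(0.3) * rng.normal(0, 1, n))
            for _ in range(4)
        ]
        noise = 1.0 + 0.2 * rng.normal(0, 1, n)
        col = self._collection(good + [noise])
        retained, rejected, r = leave_one_out_screen(col)
        assert rejected == ["T4"]
        assert len(retained.trees) == 4

    def test_zero_threshold_rejects_nothing(self):
        rng = np.random.default_rng(7)
        col = self._collection([1 + 0.2 * rng.normal(0, 1, 60) for _ in range(5)])
        _, rejected, _ = leave_one_out_screen(col, r_min=0.0)
        assert rejected == []
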