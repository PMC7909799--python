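"""Tucson/CSV readers, writers and core-to-tree averaging."""

import numpy as np
import pandas as pd
import pytest

from defolyr.io import (
    RawSeries,
    RwlParseError,
    average_cores_per_tree,
    read_climate_csv,
    read_rwl,
    read_seasonal_csv,
    write_rwl,
    write_seasonal_csv,
)
from conftest import make_tree


class TestReadRwl:
    def test_hand_decoded_toy_block(self, tmp_path):
        # hand decode: three values in 0.01 mm, then the 999 stop marker
        p = tmp_path / "toy.rwl"
        p.write_text("TST01 1990 100 200 300 999\n")
        series = read_rwl(p)
        assert len(series) == 1
        s = series[0]
        assert s.series_id == "TST01"
        assert s.first_year == 1990
        np.testing.assert_allclose(s.widths, [1.00, 2.00, 3.00])

    def test_sentinel_minus_9999_switches_units(self, tmp_path):
        p = tmp_path / "toy.rwl"
        p.write_text("TST01 1990 100 200 300 -9999\n")
        s = read_rwl(p)[0]
        np.testing.assert_allclose(s.widths, [0.100, 0.200, 0.300])

    def test_round_trip_preserves_years_and_values(self, tmp_path):
        rng = np.random.default_rng(7)
        series = [
            RawSeries("A01", 1903, np.round(rng.uniform(0.2, 3.0, 45), 2)),
            RawSeries("B01", 1950, np.round(rng.uniform(0.2, 3.0, 30), 2)),
        ]
        p = tmp_path / "rt.rwl"
        write_rwl(p, series)
        back = read_rwl(p)
        for orig, new in zip(series, back):
            assert orig.series_id == new.series_id
            assert orig.first_year == new.first_year
            np.testing.assert_allclose(orig.widths, new.widths, atol=0.005)

    def test_missing_ring_zero_is_flagged(self, tmp_path):
        p = tmp_path / "m.rwl"
        p.write_text("TST01 1990 100 0 300 999\n")
        s = read_rwl(p)[0]
        assert list(s.missing_flags) == [False, True, False]

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.rwl"
        p.write_text("TST01 1990 100 200\nTST01 abc 300 999\n")
        with pytest.raises(RwlParseError, match="line 2"):
            read_rwl(p)

    def test_duplicate_series_after_stop_marker_rejected(self, tmp_path):
        p = tmp_path / "dup.rwl"
        p.write_text("TST01 1990 100 999\nTST01 1990 100 999\n")
        with pytest.raises(RwlParseError, match="duplicate"):
            read_rwl(p)


class TestSeasonalCsv:
    def test_total_is_sum_of_fractions(self, tmp_path):
        p = tmp_path / "s.csv"
        pd.DataFrame(
            {
                "tree": ["t1"] * 3,
                "core": ["c1"] * 3,
                "year": [2000, 2001, 2002],
                "earlywood": [1.0, 1.0, 1.0],
                "latewood": [0.5, 0.5, 0.5],
            }
        ).to_csv(p, index=False)
        series = read_seasonal_csv(p)
        assert len(series) == 1
        np.testing.assert_allclose(series[0].total, [1.5, 1.5, 1.5])

    def test_duplicate_core_year_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        pd.DataFrame(
            {
                "tree": ["t1"] * 2,
                "core": ["c1"] * 2,
                "year": [2000, 2000],
                "earlywood": [1.0, 1.0],
                "latewood": [0.5, 0.5],
            }
        ).to_csv(p, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_seasonal_csv(p)

    def test_non_consecutive_years_rejected(self, tmp_path):
        p = tmp_path / "g.csv"
        pd.DataFrame(
            {
                "tree": ["t1"] * 2,
                "core": ["c1"] * 2,
                "year": [2000, 2002],
                "earlywood": [1.0, 1.0],
                "latewood": [0.5, 0.5],
            }
        ).to_csv(p, index=False)
        with pytest.raises(ValueError, match="non-consecutive"):
            read_seasonal_csv(p)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("tree,core,year,earlywood,latewood\n")
        assert read_seasonal_csv(p) == []

    def test_round_trip(self, tmp_path):
        t = make_tree("t1", 1990, [1.0, 1.1, 1.2], [0.4, 0.3, 0.2])
        p = tmp_path / "rt.csv"
        write_seasonal_csv(p, [t])
        back = read_seasonal_csv(p)[0]
        np.testing.assert_allclose(back.earlywood, t.earlywood)
        np.testing.assert_allclose(back.latewood, t.latewood)
        assert back.first_year == t.first_year


class TestAverageCores:
    def test_identical_cores_idempotent(self):
        c = make_tree("t1", 1990, [1.0, 1.1], [0.5, 0.4])
        out = average_cores_per_tree([c, c])
        np.testing.assert_allclose(out.earlywood, c.earlywood)
        np.testing.assert_allclose(out.total, c.total)

    def test_arithmetic_mean(self):
        a = make_tree("t1", 1990, [2, 2, 2], [1, 1, 1])
        b = make_tree("t1", 1990, [4, 4, 4], [2, 2, 2])
        out = average_cores_per_tree([a, b])
        np.testing.assert_allclose(out.earlywood, [3, 3, 3])
        np.testing.assert_allclose(out.total, [4.5, 4.5, 4.5])

    def test_offset_spans_mean_only_on_overlap(self):
        # hand computation: mean over 1995-1999, single-core values elsewhere
        a = make_tree("t1", 1990, np.full(10, 2.0), np.full(10, 1.0))  # 1990-1999
        b = make_tree("t1", 1995, np.full(10, 4.0), np.full(10, 2.0))  # 1995-2004
        out = average_cores_per_tree([a, b])
        assert out.first_year == 1990 and out.last_year == 2004
        np.testing.assert_allclose(out.earlywood[:5], 2.0)   # 1990-1994
        np.testing.assert_allclose(out.earlywood[5:10], 3.0)  # 1995-1999
        np.testing.assert_allclose(out.earlywood[10:], 4.0)  # 2000-2004

    def test_disjoint_spans_refused(self):
        a = make_tree("t1", 1990, [1, 1], [1, 1])
        b = make_tree("t1", 2000, [1, 1], [1, 1])
        with pytest.raises(ValueError, match="overlap"):
            average_cores_per_tree([a, b])

    def test_output_satisfies_seasonal_sum_invariant(self):
        rng = np.random.default_rng(3)
        cores = [
            make_tree("t1", 1990 + off, rng.uniform(0.5, 2, 30), rng.uniform(0.1, 1, 30))
            for off in (0, 5, 10)
        ]
        out = average_cores_per_tree(cores)
        np.testing.assert_allclose(out.total, out.earlywood + out.latewood, atol=0.01)


def test_climate_csv_rejects_interior_gaps(tmp_path):
    rows = [
        {"year": y, "month": m, "temperature": 1.0, "precipitation": 10.0}
        for y in (2000, 2001, 2002)
        for m in range(1, 13)
    ]
    df = pd.DataFrame(rows)
    p = tmp_path / "c.csv"
    df.to_csv(p, index=False)
    assert len(read_climate_csv(p)) == 36
    df.drop(index=[15]).to_csv(p, index=False)  # hole inside 2001
    with pytest.raises(ValueError, match="gaps"):
        read_climate_csv(p)
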