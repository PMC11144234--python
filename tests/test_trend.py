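"""Sen's slope, compositing, greening/browning fractions and plots."""

import csv
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from postfire import (IndexRaster, InputError, TrendSeries,
                      annual_max_composite, evi_trend_plot, greening_browning,
                      sens_slope, slope_histogram, slope_raster)


def brute_force_sens(times, values):
    """Independent oracle: explicit enumeration of all C(n,2) pair slopes."""
    slopes = sorted((values[j] - values[i]) / (times[j] - times[i])
                    for i, j in combinations(range(len(times)), 2))
    m = len(slopes)
    mid = m // 2
    return slopes[mid] if m % 2 else (slopes[mid - 1] + slopes[mid]) / 2


class TestSensSlope:
    @pytest.mark.parametrize("times,values,expected", [
        ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
        ([1, 2, 3], [0.5, 0.5, 0.5], 0.0),
        ([1, 2, 3], [1, 3, 2], 0.5),  # pair slopes {2, 0.5, -1}
    ])
    def test_known_series(self, times, values, expected):
        assert sens_slope(TrendSeries(times, values)) == expected

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            t = np.sort(rng.choice(np.arange(2000, 2100), n, replace=False))
            x = rng.normal(size=n)
            s = TrendSeries(t.astype(float), x)
            assert sens_slope(s) == brute_force_sens(t.astype(float), x)

    def test_matches_scipy_theilslopes(self):
        rng = np.random.default_rng(3)
        t = np.arange(2000, 2012, dtype=float)
        x = rng.normal(size=t.size)
        ours = sens_slope(TrendSeries(t, x))
        ref = stats.theilslopes(x, t).slope
        assert ours == pytest.approx(ref, rel=1e-12)

    @given(st.floats(-0.5, 0.5), st.floats(-1, 1), st.integers(3, 20))
    @settings(max_examples=50, deadline=None)
    def test_exact_linear_series_recovers_slope(self, b, a, n):
        t = np.arange(2000, 2000 + n, dtype=float)
        x = a + b * (t - 2000)
        assert sens_slope(TrendSeries(t, x)) == pytest.approx(b, abs=1e-12)

    def test_duplicate_times_rejected(self):
        with pytest.raises(InputError):
            TrendSeries([2000, 2000, 2001], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            TrendSeries([2000], [1.0])


class TestComposite:
    def test_single_raster_identity(self):
        r = IndexRaster(np.full((3, 3), 0.4))
        out = annual_max_composite({2001: [r]})
        np.testing.assert_array_equal(out[2001].values, r.values)

    def test_nodata_aware_max(self):
        a = IndexRaster(np.full((1, 1), 0.2))
        b = IndexRaster(np.full((1, 1), 0.5))
        c = IndexRaster(np.zeros((1, 1)), nodata_mask=np.ones((1, 1), bool))
        out = annual_max_composite({2001: [a, b, c]})
        assert out[2001].values[0, 0] == 0.5
        assert not out[2001].nodata_mask[0, 0]

    def test_all_nodata_pixel_stays_nodata(self):
        c = IndexRaster(np.zeros((1, 1)), nodata_mask=np.ones((1, 1), bool))
        out = annual_max_composite({2001: [c, c]})
        assert out[2001].nodata_mask[0, 0]

    def test_empty_year_dropped(self):
        r = IndexRaster(np.zeros((2, 2)))
        out = annual_max_composite({2001: [r], 2002: []})
        assert set(out) == {2001}


class TestSlopeRaster:
    def test_exact_linear_stack(self):
        yearly = {2000 + t: IndexRaster(np.full((4, 4), 0.1 + 0.01 * t))
                  for t in range(6)}
        out = slope_raster(yearly)
        np.testing.assert_allclose(out.values, 0.01, atol=1e-12)

    def test_single_valid_year_is_nodata(self):
        masked = np.ones((2, 2), bool)
        masked[0, 0] = False
        yearly = {
            2000: IndexRaster(np.full((2, 2), 0.3), nodata_mask=np.zeros((2, 2), bool)),
            2001: IndexRaster(np.full((2, 2), 0.4), nodata_mask=masked),
            2002: IndexRaster(np.full((2, 2), 0.5), nodata_mask=masked),
        }
        out = slope_raster(yearly)
        assert not out.nodata_mask[0, 0]
        assert out.nodata_mask[1, 1]  # only 2000 valid there

    def test_matches_per_pixel_brute_force(self):
        rng = np.random.default_rng(5)
        years = list(range(2000, 2008))
        yearly = {}
        for y in years:
            vals = rng.uniform(-0.5, 0.5, (16, 16))
            mask = rng.random((16, 16)) < 0.15
            yearly[y] = IndexRaster(vals, nodata_mask=mask)
        out = slope_raster(yearly)
        t = np.asarray(years, float)
        for r in range(16):
            for c in range(16):
                vals = np.array([yearly[y].values[r, c] for y in years])
                ok = np.array([~yearly[y].nodata_mask[r, c] for y in years])
                if ok.sum() < 2:
                    assert out.nodata_mask[r, c]
                else:
                    expected = brute_force_sens(t[ok], vals[ok])
                    assert out.values[r, c] == pytest.approx(expected, abs=1e-12)

    def test_needs_two_years(self):
        with pytest.raises(InputError):
            slope_raster({2000: IndexRaster(np.zeros((2, 2)))})


class TestGreeningBrowning:
    def _slopes(self, values):
        return IndexRaster(np.asarray(values, float), index_name="slope",
                           pixel_size_m=250.0)

    def test_known_fractions(self):
        vals = np.concatenate([np.full(60, 0.01), np.full(40, -0.01)])
        s = greening_browning(self._slopes(vals.reshape(10, 10)))
        assert s.greening_fraction == pytest.approx(0.6)
        assert s.browning_fraction == pytest.approx(0.4)
        assert s.neutral_fraction == pytest.approx(0.0)

    def test_area_arithmetic_at_250m(self):
        vals = np.zeros((5, 5))
        vals.flat[:16] = 0.02  # 16 greening pixels at 250 m -> 1 km^2
        s = greening_browning(self._slopes(vals))
        assert s.greening_km2 == pytest.approx(16 * 0.0625)
        assert s.greening_km2 == pytest.approx(1.0)

    def test_zero_band_absorbs_small_slopes(self):
        vals = np.full((4, 4), 1e-4)
        s = greening_browning(self._slopes(vals), zero_band=1e-3)
        assert s.greening_fraction == 0.0
        assert s.browning_fraction == 0.0
        assert s.neutral_fraction == 1.0

    def test_fractions_partition_unmasked_pixels(self):
        rng = np.random.default_rng(8)
        r = IndexRaster(rng.normal(0, 0.01, (12, 12)), index_name="slope",
                        nodata_mask=rng.random((12, 12)) < 0.2)
        s = greening_browning(r, zero_band=0.005)
        assert s.greening_fraction + s.browning_fraction + s.neutral_fraction \
            == pytest.approx(1.0)

    def test_area_scales_quadratically_with_pixel_size(self):
        vals = np.full((4, 4), 0.02)
        s1 = greening_browning(self._slopes(vals), pixel_size_m=250.0)
        s2 = greening_browning(self._slopes(vals), pixel_size_m=500.0)
        assert s2.greening_km2 == pytest.approx(4 * s1.greening_km2)

    def test_negative_zero_band_rejected(self):
        with pytest.raises(InputError):
            greening_browning(self._slopes(np.zeros((2, 2))), zero_band=-0.1)


class TestHistogramAndPlot:
    def test_counts_conserved(self, trend_stack, tmp_path):
        yearly, _ = trend_stack
        slopes = slope_raster(yearly)
        counts, _ = slope_histogram(slopes, bins=30,
                                    plot_path=tmp_path / "h.png")
        assert counts.sum() == slopes.valid.sum()
        assert (tmp_path / "h.png").exists()

    def test_constant_raster_single_bin(self):
        r = IndexRaster(np.full((4, 4), 0.01), index_name="slope")
        counts, _ = slope_histogram(r, bins=10)
        assert (counts > 0).sum() == 1

    def test_bimodal_synthetic_stack(self, trend_stack):
        yearly, truth = trend_stack
        counts, edges = slope_histogram(slope_raster(yearly), bins=40)
        centers = (edges[:-1] + edges[1:]) / 2
        occupied = centers[counts > 0.01 * counts.sum()]
        assert occupied.min() == pytest.approx(-0.01, abs=0.003)
        assert occupied.max() == pytest.approx(0.01, abs=0.003)

    def test_trend_plot_and_csv(self, tmp_path):
        yearly = {2000 + t: IndexRaster(np.full((3, 3), 0.1 + 0.05 * t))
                  for t in range(5)}
        yr, means = evi_trend_plot(yearly, plot_path=tmp_path / "t.png",
                                   csv_path=tmp_path / "t.csv")
        assert np.all(np.diff(means) > 0)
        assert means[0] == pytest.approx(0.1)
        with open(tmp_path / "t.csv") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == 1 + 5
        assert (tmp_path / "t.png").exists()
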