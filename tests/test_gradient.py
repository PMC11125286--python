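"""Bin schemes, time binning, and the intensity-gradient regression."""

import numpy as np
import pytest

from igradient.core import wear_minutes
from igradient.gradient import (
    BinnedTime,
    bin_occupancy_ratio,
    bin_time,
    compute_ig,
    first_bin_composition,
    make_bin_scheme,
    merge_binned,
    trim_binned,
)

from conftest import make_series


class TestSchemes:
    @pytest.mark.parametrize("variant,units,width,n_closed", [
        ("acc", "mg", 25.0, 160),
        ("count_fine", "counts", 25.0, 160),
        ("count_adjusted", "counts", 100.0, 40),
    ])
    def test_structure(self, variant, units, width, n_closed):
        s = make_bin_scheme(variant)
        assert (s.units, s.width, s.n_closed_bins) == (units, width, n_closed)
        assert s.n_closed_bins * s.width == 4000
        assert s.n_bins == n_closed + 1
        assert np.all(np.diff(s.edges) > 0)

    def test_first_bin_midpoint(self):
        assert make_bin_scheme("acc").midpoints[0] == 12.5
        assert make_bin_scheme("count_adjusted").midpoints[0] == 50.0

    def test_terminal_midpoint(self):
        assert make_bin_scheme("count_fine").midpoints[-1] == 4012.5

    def test_unknown_variant_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            make_bin_scheme("freedson")


class TestBinTime:
    def test_low_counts_in_first_adjusted_bin(self):
        s = make_series([0, 12, 24])
        b = bin_time(s, make_bin_scheme("count_adjusted"))
        assert b.minutes[0] == 0.75
        assert b.minutes[1:].sum() == 0

    def test_boundary_4000_in_terminal_bin(self):
        b = bin_time(make_series([4000]), make_bin_scheme("count_fine"))
        assert b.minutes[-1] == 0.25

    def test_uniform_coverage_occupies_all_closed_bins(self):
        vals = np.arange(40) * 100 + 50
        b = bin_time(make_series(vals), make_bin_scheme("count_adjusted"))
        assert b.occupied_bins == 40

    def test_conservation(self, rng):
        for scheme in ("count_fine", "count_adjusted"):
            for _ in range(10):
                n = int(rng.integers(10, 400))
                s = make_series(rng.integers(0, 6000, n), wear=rng.random(n) < 0.7)
                b = bin_time(s, make_bin_scheme(scheme))
                assert b.minutes.sum() == pytest.approx(wear_minutes(s))

    def test_unit_mismatch_errors(self):
        s = make_series([1.0, 2.0], units="mg")
        with pytest.raises(ValueError, match="units"):
            bin_time(s, make_bin_scheme("count_fine"))

    def test_adjusted_equals_fine_aggregated_4fold(self, rng):
        fine = make_bin_scheme("count_fine")
        adj = make_bin_scheme("count_adjusted")
        for _ in range(25):
            n = int(rng.integers(5, 600))
            s = make_series(rng.integers(0, 5000, n), wear=rng.random(n) < 0.8)
            bf = bin_time(s, fine).minutes
            ba = bin_time(s, adj).minutes
            agg = bf[:-1].reshape(40, 4).sum(axis=1)
            np.testing.assert_array_equal(ba[:-1], agg)
            assert ba[-1] == bf[-1]


class TestComputeIg:
    def test_two_bin_closed_form(self):
        # minutes 100 and 10 at midpoints 50 and 150: slope = ln(0.1)/ln(3)
        scheme = make_bin_scheme("count_adjusted")
        minutes = np.zeros(scheme.n_bins)
        minutes[0], minutes[1] = 100.0, 10.0
        ig = compute_ig(BinnedTime(scheme, minutes, 0))
        assert ig.slope == pytest.approx(np.log(0.1) / np.log(3.0), abs=1e-12)
        assert ig.n_bins_used == 2

    @pytest.mark.parametrize("variant", ["acc", "count_fine", "count_adjusted"])
    @pytest.mark.parametrize("beta", [-1.0, -2.0, -2.5])
    def test_exact_power_law_recovered(self, variant, beta):
        scheme = make_bin_scheme(variant)
        minutes = 500.0 * scheme.midpoints ** beta
        ig = compute_ig(BinnedTime(scheme, minutes, 0))
        assert ig.slope == pytest.approx(beta, abs=1e-9)
        assert ig.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_distribution_zero_slope(self):
        scheme = make_bin_scheme("count_fine")
        ig = compute_ig(BinnedTime(scheme, np.full(scheme.n_bins, 3.0), 0))
        assert ig.slope == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_errors(self):
        scheme = make_bin_scheme("count_fine")
        minutes = np.zeros(scheme.n_bins)
        minutes[5] = 10
        with pytest.raises(ValueError, match="fewer than 2"):
            compute_ig(BinnedTime(scheme, minutes, 0))

    def test_scale_invariance_of_slope(self, rng):
        scheme = make_bin_scheme("count_adjusted")
        minutes = np.zeros(scheme.n_bins)
        occ = rng.choice(scheme.n_bins, 15, replace=False)
        minutes[occ] = rng.random(15) * 50 + 1
        ig1 = compute_ig(BinnedTime(scheme, minutes, 0))
        ig2 = compute_ig(BinnedTime(scheme, minutes * 7.5, 0))
        assert ig2.slope == pytest.approx(ig1.slope, abs=1e-12)
        assert ig2.intercept != pytest.approx(ig1.intercept)

    def test_pseudo_minutes_includes_empty_bins(self):
        scheme = make_bin_scheme("count_adjusted")
        minutes = np.zeros(scheme.n_bins)
        minutes[0], minutes[3] = 10.0, 1.0
        ig = compute_ig(BinnedTime(scheme, minutes, 0), pseudo_minutes=0.01)
        assert ig.n_bins_used == scheme.n_bins


class TestDiagnostics:
    def test_equal_occupancy_ratio_one(self):
        fine = make_bin_scheme("count_fine")
        acc = make_bin_scheme("acc")
        m = np.zeros(fine.n_bins)
        m[:10] = 1.0
        ratio = bin_occupancy_ratio(BinnedTime(fine, m, 0), BinnedTime(acc, m.copy(), 0))
        assert ratio == 1.0

    def test_ratio_arithmetic(self):
        fine = make_bin_scheme("count_fine")
        acc = make_bin_scheme("acc")
        mc = np.zeros(fine.n_bins)
        mc[:46] = 1.0
        ma = np.zeros(acc.n_bins)
        ma[:20] = 1.0
        assert bin_occupancy_ratio(BinnedTime(fine, mc, 0), BinnedTime(acc, ma, 0)) == 2.3

    def test_zero_denominator_errors(self):
        fine = make_bin_scheme("count_fine")
        acc = make_bin_scheme("acc")
        m = np.zeros(fine.n_bins)
        m[0] = 1
        with pytest.raises(ValueError):
            bin_occupancy_ratio(BinnedTime(fine, m, 0), BinnedTime(acc, np.zeros(acc.n_bins), 0))

    @pytest.mark.parametrize("counts,expected", [
        ([0, 0, 0, 0], 0.0),
        ([10, 30, 50, 90], 0.75),
        ([25, 40, 99], 1.0),
    ])
    def test_first_bin_light_fraction(self, counts, expected):
        s = make_series(counts)
        frac = first_bin_composition(s, make_bin_scheme("count_adjusted"))
        assert frac == expected

    def test_first_bin_empty_errors(self):
        s = make_series([500, 600])
        with pytest.raises(ValueError, match="empty"):
            first_bin_composition(s, make_bin_scheme("count_adjusted"))


class TestHelpers:
    def test_merge_pools_minutes(self, rng):
        scheme = make_bin_scheme("count_adjusted")
        parts = [bin_time(make_series(rng.integers(0, 3000, 50)), scheme)
                 for _ in range(3)]
        merged = merge_binned(parts)
        np.testing.assert_allclose(merged.minutes,
                                   np.sum([p.minutes for p in parts], axis=0))
        assert merged.n_epochs_binned == 150

    def test_trim_zeroes_partial_edge_bins(self):
        scheme = make_bin_scheme("count_adjusted")
        minutes = np.ones(scheme.n_bins)
        trimmed = trim_binned(BinnedTime(scheme, minutes, 0), 150.0, 3950.0)
        # bins [100,200) and [3900,4000) straddle the support edges
        assert trimmed.minutes[1] == 0 and trimmed.minutes[39] == 0
        assert trimmed.minutes[-1] == 0  # terminal bin outside support
        assert trimmed.minutes[2:39].sum() == 37
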