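"""Unit and property tests for the statistical primitives."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raincloudpy import (
    Sample,
    ash_density,
    box_stats,
    kde_density,
    nrd0_bandwidth,
    summary_se,
    summary_se_frame,
)

# published two-sided 95% Student-t critical value, 3 df
T_975_DF3 = 3.182446


class TestSample:
    def test_drops_and_counts_nonfinite(self):
        s = Sample([1.0, np.nan, 2.0, np.inf, 3.0])
        assert s.n == 3
        assert s.n_dropped == 2
        np.testing.assert_array_equal(s.values, [1.0, 2.0, 3.0])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            Sample([np.nan, np.nan])


class TestNrd0:
    def test_reference_value_1_to_10(self):
        # 0.9 * min(sd=3.02765, IQR/1.34=4.5/1.34) * 10**-0.2
        assert nrd0_bandwidth(Sample(range(1, 11))) == pytest.approx(1.7193, abs=1e-4)

    def test_full_fallback_chain_constant_zero(self):
        # sd = 0, IQR = 0, first value 0 -> L = 1
        assert nrd0_bandwidth(Sample([0, 0, 0, 0])) == pytest.approx(
            0.9 * 4 ** (-0.2), rel=1e-12
        )

    @pytest.mark.parametrize("c", [3.0, -2.5, 0.25])
    def test_fallback_to_first_value_for_constant_data(self, c):
        assert nrd0_bandwidth(Sample([c, c])) == pytest.approx(
            0.9 * abs(c) * 2 ** (-0.2), rel=1e-12
        )

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            nrd0_bandwidth(Sample([1.0]))


class TestKde:
    def test_single_point_peak_is_gaussian_height(self):
        # odd gridsize puts a grid point exactly on the observation
        curve = kde_density(Sample([0.0]), bandwidth=1.0, cut=3.0, gridsize=301)
        assert curve.density.max() == pytest.approx(1.0 / math.sqrt(2 * math.pi), rel=1e-6)
        assert curve.grid[np.argmax(curve.density)] == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_sample_gives_symmetric_density(self):
        curve = kde_density(Sample([-1.0, 1.0]), bandwidth=0.7, cut=3.0, gridsize=201)
        np.testing.assert_allclose(curve.density, curve.density[::-1], rtol=1e-10)

    def test_mass_conservation(self, rng):
        x = Sample(rng.normal(size=50))
        curve = kde_density(x, bandwidth=0.4, cut=4.0, gridsize=512)
        assert curve.integral() >= 0.999
        assert abs(1.0 - curve.integral()) < 1e-3

    def test_translation_equivariance(self, rng):
        x = rng.normal(size=40)
        c = 17.25
        base = kde_density(Sample(x), 0.5, cut=3.0, gridsize=128)
        moved = kde_density(Sample(x + c), 0.5, cut=3.0, gridsize=128)
        np.testing.assert_allclose(moved.grid, base.grid + c, rtol=1e-12, atol=1e-9)
        np.testing.assert_allclose(moved.density, base.density, rtol=1e-9)

    def test_trim_restricts_grid_to_data_range(self, rng):
        x = rng.normal(size=30)
        curve = kde_density(Sample(x), 0.5, cut=3.0, trim=True)
        assert curve.grid[0] == pytest.approx(x.min())
        assert curve.grid[-1] == pytest.approx(x.max())
        assert curve.trimmed

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            kde_density(Sample([1.0, 2.0]), bandwidth=0.0)

    def test_scipy_cross_check(self, rng):
        # independent route: scipy's KDE evaluated at our grid with our bandwidth
        from scipy.stats import gaussian_kde

        x = rng.normal(size=80)
        h = 0.45
        ours = kde_density(Sample(x), h, cut=3.0, gridsize=101)
        ref = gaussian_kde(x, bw_method=h / x.std(ddof=1))(ours.grid)
        np.testing.assert_allclose(ours.density, ref, rtol=1e-8)


class TestAsh:
    def test_one_shift_equals_plain_histogram(self, rng):
        x = rng.normal(size=60)
        bw = 0.5
        curve = ash_density(Sample(x), bw, n_shifts=1)
        # brute-force histogram density at each output cell center
        lo = x.min() - bw
        for center, dens in zip(curve.grid, curve.density):
            k = int(np.floor((center - lo) / bw))
            count = np.sum((x >= lo + k * bw) & (x < lo + (k + 1) * bw))
            assert dens == pytest.approx(count / (x.size * bw), rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("bw", [0.2, 0.5, 1.3])
    def test_mass_and_nonnegativity(self, rng, bw):
        curve = ash_density(Sample(rng.normal(size=100)), bw, n_shifts=32)
        assert curve.density.min() >= 0
        assert curve.integral() == pytest.approx(1.0, abs=0.01)

    def test_many_shifts_converge_to_triangular_kernel(self, rng):
        x = rng.normal(size=100)
        h = 0.5
        curve = ash_density(Sample(x), h, n_shifts=64)
        tri = (
            np.maximum(0.0, 1.0 - np.abs(curve.grid[:, None] - x[None, :]) / h)
        ).sum(axis=1) / (x.size * h)
        assert np.max(np.abs(curve.density - tri)) < 0.02 * tri.max()

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            ash_density(Sample([1.0, 2.0]), bin_width=-1.0)


def _quantile_type7(sorted_vals, q):
    """Independent order-statistic interpolation (no numpy.quantile)."""
    n = len(sorted_vals)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def _box_oracle(values, k=1.5):
    s = sorted(values)
    q1 = _quantile_type7(s, 0.25)
    med = _quantile_type7(s, 0.50)
    q3 = _quantile_type7(s, 0.75)
    lo_f, hi_f = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
    inside = [v for v in s if lo_f <= v <= hi_f]
    out = [v for v in s if v < lo_f or v > hi_f]
    return q1, med, q3, min(inside), max(inside), out


class TestBoxStats:
    @pytest.mark.parametrize(
        "data, expected",
        [
            ([1, 2, 3, 4, 5], (2, 3, 4, 1, 5, [])),
            ([1, 2, 3, 4, 100], (2, 3, 4, 1, 4, [100])),
            ([7, 7, 7], (7, 7, 7, 7, 7, [])),
        ],
    )
    def test_reference_cases(self, data, expected):
        bs = box_stats(Sample(data))
        q1, med, q3, wlo, whi, out = expected
        assert (bs.q1, bs.median, bs.q3) == (q1, med, q3)
        assert (bs.whisker_lo, bs.whisker_hi) == (wlo, whi)
        assert list(bs.outliers) == out

    def test_exhaustive_small_integer_samples(self):
        # every multiset of size 1..8 over {0..4} against the sort oracle
        for n in range(1, 9):
            for combo in itertools.combinations_with_replacement(range(5), n):
                bs = box_stats(Sample(combo))
                q1, med, q3, wlo, whi, out = _box_oracle(combo)
                assert bs.q1 == pytest.approx(q1, abs=1e-12)
                assert bs.median == pytest.approx(med, abs=1e-12)
                assert bs.q3 == pytest.approx(q3, abs=1e-12)
                assert bs.whisker_lo == wlo and bs.whisker_hi == whi
                assert sorted(bs.outliers) == sorted(out)

    def test_ordering_invariant(self, rng):
        v = rng.normal(size=37)
        bs = box_stats(Sample(v))
        assert bs.whisker_lo <= bs.q1 <= bs.median <= bs.q3 <= bs.whisker_hi


class TestSummarySE:
    def test_known_four_point_group(self):
        df = pd.DataFrame({"g": ["a"] * 4, "y": [1.0, 2.0, 3.0, 4.0]})
        (row,) = summary_se(df, "y", "g")
        assert row.N == 4
        assert row.mean == pytest.approx(2.5)
        assert row.sd == pytest.approx(1.290994, abs=1e-6)
        assert row.se == pytest.approx(0.645497, abs=1e-6)
        assert row.ci == pytest.approx(0.645497 * T_975_DF3, rel=1e-5)

    def test_constant_group_has_zero_spread(self):
        df = pd.DataFrame({"g": ["a"] * 3, "y": [5.0, 5.0, 5.0]})
        (row,) = summary_se(df, "y", "g")
        assert row.sd == row.se == row.ci == 0.0

    def test_se_and_ci_identities(self, rng):
        # se*sqrt(N) == sd and ci/se == t quantile across a range of N
        from scipy.stats import t as t_dist

        for n in [2, 3, 10, 57, 500]:
            df = pd.DataFrame({"g": ["a"] * n, "y": rng.normal(size=n)})
            (row,) = summary_se(df, "y", "g")
            assert row.se * math.sqrt(n) == pytest.approx(row.sd, rel=1e-12)
            assert row.ci / row.se == pytest.approx(
                t_dist.ppf(0.975, n - 1), rel=1e-9
            )

    def test_single_observation_group_warns_and_reports_nan(self):
        df = pd.DataFrame({"g": ["a"], "y": [3.0]})
        with pytest.warns(UserWarning):
            (row,) = summary_se(df, "y", "g")
        assert row.N == 1 and math.isnan(row.sd) and math.isnan(row.ci)

    def test_unknown_column_raises_with_available(self):
        df = pd.DataFrame({"g": ["a"], "y": [1.0]})
        with pytest.raises(KeyError, match="scor"):
            summary_se(df, "scor", "g")

    def test_multi_factor_grouping_and_frame(self, factorial_table):
        frame = summary_se_frame(factorial_table, "score", ["group", "time"])
        assert list(frame.columns) == [
            "group", "time", "N", "score_mean", "score_median", "sd", "se", "ci",
        ]
        assert frame["N"].tolist() == [18, 18, 18, 11, 11, 11]

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_se_recovers_sd_property(self, values):
        df = pd.DataFrame({"g": ["a"] * len(values), "y": values})
        (row,) = summary_se(df, "y", "g")
        if row.sd > 0:
            assert row.se * math.sqrt(row.N) == pytest.approx(row.sd, rel=1e-12)
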