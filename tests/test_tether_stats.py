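"""Binomial proportions, Poisson rates and tests, histograms, Gaussian
fits, and unfolding arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta, norm

import tetherforce as tf
from tetherforce.tether_stats import (
    StepHistogram,
    clopper_pearson,
    fit_gaussian_peak,
    step_histogram,
)


class TestBinProportions:
    def test_degenerate_bins(self):
        t = np.full(20, 5.0)
        bins = tf.bin_proportions(t, np.zeros(20, bool))
        assert bins[0].p_fc == 0.0 and bins[0].ci68[0] == 0.0
        bins = tf.bin_proportions(t, np.ones(20, bool))
        assert bins[0].p_fc == 1.0 and bins[0].ci68[1] == 1.0

    def test_interval_matches_beta_quantile_oracle(self):
        lo, hi = clopper_pearson(3, 10)
        assert lo == pytest.approx(beta.ppf(0.16, 3, 8), abs=1e-12)
        assert hi == pytest.approx(beta.ppf(0.84, 4, 7), abs=1e-12)

    def test_binning_and_moments(self):
        t = np.array([5.0, 7.0, 15.0, 17.0, 19.0])
        f = np.array([True, False, True, True, False])
        bins = tf.bin_proportions(t, f, bin_width=10.0)
        assert len(bins) == 2  # empty bins omitted
        assert bins[0].n == 2 and bins[0].k == 1
        assert bins[1].t_mean == pytest.approx(17.0)
        assert bins[1].p_fc == pytest.approx(2.0 / 3.0)

    @pytest.mark.parametrize("n", [5, 10, 50])
    def test_empirical_coverage_at_least_68(self, n):
        """Exact central intervals cover the truth in >= 68% of draws."""
        rng = np.random.default_rng(n)
        p = 0.37
        ks = rng.binomial(n, p, 10000)
        lo = np.where(ks == 0, 0.0, beta.ppf(0.16, ks, n - ks + 1))
        hi = np.where(ks == n, 1.0, beta.ppf(0.84, ks + 1, n - ks))
        coverage = np.mean((lo <= p) & (p <= hi))
        assert coverage >= 0.68


class TestLinearTrend:
    def _bins(self, x, y):
        return [
            tf.tether_stats.BinnedProportion(
                bin_label=str(i), t_mean=xx, t_sd=1.0, n=10, k=int(10 * yy),
                p_fc=yy, ci68=(max(yy - 0.2, 0.0), min(yy + 0.2, 1.0)),
            )
            for i, (xx, yy) in enumerate(zip(x, y))
        ]

    def test_collinear_exact(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        y = 0.1 + 0.0077 * x
        slope, intercept, _ = tf.linear_trend(self._bins(x, y))
        assert slope == pytest.approx(0.0077, abs=1e-12)
        assert intercept == pytest.approx(0.1, abs=1e-10)

    def test_constant_zero_slope(self):
        x = np.array([10.0, 20.0, 30.0])
        slope, _, _ = tf.linear_trend(self._bins(x, [0.4, 0.4, 0.4]))
        assert slope == 0.0

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            tf.linear_trend(self._bins([1.0, 2.0], [0.1, 0.2]))

    def test_monte_carlo_recovery(self):
        from tetherforce.pipeline import simulate_binned_trend

        slope, se, _ = simulate_binned_trend(n_segments=600, seed=5)
        assert abs(slope - 0.0077) <= 2.0 * se


class TestEventRate:
    @pytest.mark.parametrize(
        "n, T, rate, se",
        [(53, 221.0, 0.240, 0.033), (19, 238.0, 0.080, 0.018), (0, 100.0, 0.0, 0.0)],
    )
    def test_printed_rates(self, n, T, rate, se):
        r, s = tf.event_rate(n, T)
        assert round(r, 3) == rate
        assert round(s, 3) == se

    def test_non_integer_count_rejected(self):
        with pytest.raises(ValueError):
            tf.event_rate(5.5, 100.0)


class TestPoissonRateTest:
    def test_symmetric_inputs_give_p_one(self):
        assert tf.poisson_rate_test(5, 100.0, 5, 100.0) == pytest.approx(1.0)

    def test_both_zero(self):
        assert tf.poisson_rate_test(0, 10.0, 0, 10.0) == 1.0

    def test_published_comparison(self):
        # 19 events/238 s vs 11 events/200 s
        assert tf.poisson_rate_test(19, 238.0, 11, 200.0) == pytest.approx(0.42, abs=0.05)

    @pytest.mark.parametrize("t1, t2", [(1.0, 1.0), (238.0, 200.0), (2.0, 1.0)])
    @pytest.mark.parametrize("method", ["central", "minlike"])
    def test_matches_exhaustive_enumeration(self, t1, t2, method):
        """For all totals N <= 12 the p-value equals brute-force summation
        over every binomial outcome, in both two-sided conventions."""
        p0 = t1 / (t1 + t2)
        for n_tot in range(1, 13):
            pmf = [
                math.comb(n_tot, k) * p0**k * (1 - p0) ** (n_tot - k)
                for k in range(n_tot + 1)
            ]
            for n1 in range(n_tot + 1):
                if method == "central":
                    lo = sum(pmf[: n1 + 1])
                    hi = sum(pmf[n1:])
                    expected = min(1.0, 2.0 * min(lo, hi))
                else:
                    expected = sum(p for p in pmf if p <= pmf[n1] * (1 + 1e-7))
                got = tf.poisson_rate_test(n1, t1, n_tot - n1, t2, method=method)
                assert got == pytest.approx(expected, abs=1e-10)


class TestStepHistogram:
    def test_default_grid_and_placement(self):
        h = step_histogram([4.5])
        assert h.bin_centers[0] == -8.75 and h.bin_centers[-1] == 48.75
        assert h.bin_width == 2.5
        # 4.5 falls in [2.5, 5.0), the bin centered at 3.75
        assert h.counts[np.where(h.bin_centers == 3.75)[0][0]] == 1

    def test_empty_input_all_zero(self):
        h = step_histogram([])
        assert h.counts.sum() == 0
        assert np.all(h.count_errors == 0)

    @given(st.lists(st.floats(-20.0, 70.0), max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_count_conservation(self, values):
        h = step_histogram(values)
        in_range = sum(1 for v in values if -10.0 <= v < 50.0)
        assert int(h.counts.sum()) == in_range

    def test_gaussian_draws_match_cdf_oracle(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(4.5, 3.1, 1000)
        h = step_histogram(draws)
        edges_lo = h.bin_centers - h.bin_width / 2
        edges_hi = h.bin_centers + h.bin_width / 2
        p = norm.cdf(edges_hi, 4.5, 3.1) - norm.cdf(edges_lo, 4.5, 3.1)
        expect = 1000 * p
        sd = np.sqrt(1000 * p * (1 - p))
        assert np.all(np.abs(h.counts - expect) <= 3 * sd + 1)


class TestGaussianPeakFit:
    def test_exact_model_counts_recovered(self):
        centers = -8.75 + 2.5 * np.arange(24)
        counts = 40.0 * np.exp(-((centers - 4.5) ** 2) / (2 * 3.1**2))
        h = StepHistogram(bin_centers=centers, bin_width=2.5, counts=counts)
        fit = fit_gaussian_peak(h)
        assert fit.dz_peak == pytest.approx(4.5, abs=0.01)
        assert fit.sd_peak == pytest.approx(3.1, abs=0.01)

    def test_single_bin_rejected(self):
        h = step_histogram([4.5])
        with pytest.raises(ValueError):
            fit_gaussian_peak(h)


class TestPearsonCorrelation:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert tf.pearson_correlation(x, x) == pytest.approx(1.0)
        assert tf.pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tf.pearson_correlation(np.ones(5), np.arange(5.0))

    def test_independent_variables_uncorrelated(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = rng.uniform(10, 90, 500)
            F = rng.uniform(0, 1000, 500)
            if abs(tf.pearson_correlation(t, F)) < 0.1:
                hits += 1
        assert hits >= 18


class TestUnfoldingArithmetic:
    def test_per_residue_gain(self):
        assert tf.helix_extension(1) == pytest.approx(0.215)

    def test_single_helix_range(self):
        # helical bundles carry helices of ~25-40 residues
        assert tf.helix_extension(25) == pytest.approx(5.375)
        assert tf.helix_extension(40) == pytest.approx(8.6)

    def test_zero_residues(self):
        assert tf.helix_extension(0) == 0.0
        assert tf.unfolded_contour(0) == 0.0

    def test_full_complex_contour(self):
        # 6216 residues across all eight subunits -> ~2.3 um
        total = tf.unfolded_contour(6216)
        assert total == pytest.approx(2268.84)
        assert total / 1000.0 == pytest.approx(2.3, abs=0.05)

    def test_simple_products(self):
        assert tf.unfolded_contour(1) == pytest.approx(0.365)
        assert tf.unfolded_contour(23) == pytest.approx(8.395)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tf.helix_extension(-1)
        with pytest.raises(ValueError):
            tf.unfolded_contour(-1)
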