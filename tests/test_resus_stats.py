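"""Descriptives, Wilcoxon, chi-square, splines and cluster-robust logit."""

import numpy as np
import pytest
from scipy import stats as sps

from neosuction.resus_stats import (
    ClusterLogit,
    SeparationError,
    Summary,
    chi2_2x2,
    cohort_flow,
    default_knots,
    fit_logit_cluster,
    fit_rcs_logit,
    odds_ratio,
    percent,
    probability_curve,
    rcs_basis,
    summarize,
    wald,
    wald_nonlinear,
    wald_overall,
    wilcoxon_signed_rank,
)


class TestSummarize:
    def test_per_baby_means_first(self):
        s = summarize([10, 20, 30], repeated_by_id=["A", "A", "B"])
        assert s.n == 2 and s.mean == pytest.approx(22.5)

    def test_interpolated_quartiles(self):
        s = summarize([1, 2, 3, 4])
        assert (s.median, s.q1, s.q3) == (2.5, 1.75, 3.25)

    def test_single_value(self):
        s = summarize([7])
        assert (s.mean, s.sd) == (7, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestWilcoxon:
    def test_symmetric_pair_gives_one(self):
        assert wilcoxon_signed_rank([-1, 1]) == pytest.approx(1.0)

    def test_all_positive_n5_exact(self):
        # all-positive is one of the two most extreme of the 2^5 sign
        # patterns: p = 2/32
        assert wilcoxon_signed_rank([2, 3, 4, 5, 6]) == pytest.approx(0.0625)

    def test_all_equal_mu0_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([3.0, 3.0], mu0=3.0) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_scipy_exact(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.4, 1.0, size=12)
        ours = wilcoxon_signed_rank(x)
        ref = sps.wilcoxon(x, method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("n", [15, 16, 17, 18, 19, 20])
    def test_exact_and_approximation_agree(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(0.3, 1.0, size=n)
        exact = wilcoxon_signed_rank(x)
        approx = float(
            sps.wilcoxon(x, method="approx", correction=True).pvalue
        )
        assert abs(exact - approx) < 0.02


class TestChi2:
    def test_mortality_tables_reproduce_printed_p(self):
        stat1, p1 = chi2_2x2([[9, 5], [11, 29]])
        stat2, p2 = chi2_2x2([[5, 2], [15, 32]])
        assert p1 == pytest.approx(0.014, abs=5e-4)
        assert stat1 == pytest.approx(6.02, abs=0.01)
        assert p2 == pytest.approx(0.043, abs=5e-4)
        assert stat2 == pytest.approx(4.08, abs=0.01)

    def test_balanced_table_is_null(self):
        stat, p = chi2_2x2([[10, 10], [10, 10]])
        assert stat == 0 and p == 1

    def test_zero_margin_suggests_exact_test(self):
        with pytest.raises(ValueError, match="exact"):
            chi2_2x2([[0, 0], [5, 5]])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_hand_pearson_formula(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(300):
            a, b, c, d = rng.integers(1, 40, size=4)
            stat, _ = chi2_2x2([[a, b], [c, d]])
            n = a + b + c + d
            hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert stat == pytest.approx(hand)


class TestRCS:
    def test_zero_below_first_knot(self):
        assert rcs_basis([-3, -1, 0], (0, 1, 2))[:, 1] == pytest.approx(0)

    def test_closed_form_beyond_last_knot(self):
        r = rcs_basis([3, 4, 5], (0, 1, 2))[:, 1]
        assert r == pytest.approx([3.0, 4.5, 6.0])  # constant slope 1.5

    def test_linear_beyond_outer_knots(self):
        x = np.linspace(2.5, 10, 200)
        r = rcs_basis(x, (0, 1, 2))[:, 1]
        d2 = np.diff(r, 2)
        assert np.max(np.abs(d2)) < 1e-9

    def test_second_derivative_continuous_at_knots(self):
        knots = (0.0, 1.0, 2.0)
        h = 1e-4

        def d2(x):
            vals = rcs_basis([x - h, x, x + h], knots)[:, 1]
            return (vals[0] - 2 * vals[1] + vals[2]) / h**2

        for t in knots:
            assert abs(d2(t - 5 * h) - d2(t + 5 * h)) < 0.02

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis([1.0], (0, 0, 2))

    def test_default_knots_are_decile_median_quantiles(self):
        k = default_knots(np.arange(1, 101))
        assert k == pytest.approx((10.9, 50.5, 90.1))

    def test_default_knots_need_ten_distinct(self):
        with pytest.raises(ValueError):
            default_knots([1.0] * 50)

    def test_middle_knot_is_median_for_symmetric_data(self):
        x = np.concatenate([np.linspace(-5, 5, 101)])
        assert default_knots(x)[1] == pytest.approx(0.0)


def _simulate_logit(n, beta, seed, n_clusters=None):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    eta = beta[0] + beta[1] * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    groups = rng.integers(0, n_clusters, size=n) if n_clusters else np.arange(n)
    return x, y, groups


class TestClusterLogit:
    def test_recovers_known_coefficients(self):
        x, y, g = _simulate_logit(2000, (-1.0, 0.5), seed=42, n_clusters=100)
        est = ClusterLogit().fit(x, y, groups=g)
        se = np.sqrt(np.diag(est.cov_params_))
        assert abs(est.params_[0] - (-1.0)) < 3 * se[0]
        assert abs(est.params_[1] - 0.5) < 3 * se[1]
        assert est.converged_

    def test_own_cluster_equals_hc0_times_small_sample_factor(self):
        import statsmodels.api as sm

        x, y, _ = _simulate_logit(400, (-0.5, 0.8), seed=1)
        est = ClusterLogit().fit(x, y)  # every observation its own cluster
        X = np.column_stack([np.ones_like(x), x])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        n = len(y)
        np.testing.assert_allclose(
            est.cov_params_, np.asarray(ref.cov_params()) * n / (n - 1),
            rtol=1e-4,
        )

    def test_matches_statsmodels_cluster_covariance(self):
        import statsmodels.api as sm

        x, y, g = _simulate_logit(600, (-0.5, 0.7), seed=3, n_clusters=40)
        est = ClusterLogit().fit(x, y, groups=g)
        X = np.column_stack([np.ones_like(x), x])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            cov_type="cluster", cov_kwds={"groups": g, "use_correction": True}
        )
        # statsmodels applies the Stata-style correction
        # G/(G-1) * (n-1)/(n-k); ours uses the plain G/(G-1) factor
        n, k = len(y), X.shape[1]
        np.testing.assert_allclose(
            est.cov_params_,
            np.asarray(ref.cov_params()) * (n - k) / (n - 1),
            rtol=1e-4,
        )

    def test_point_estimates_unaffected_by_clustering(self):
        x, y, g = _simulate_logit(500, (-0.5, 0.8), seed=9, n_clusters=25)
        a = ClusterLogit().fit(x, y, groups=g)
        b = ClusterLogit().fit(x, y)
        np.testing.assert_allclose(a.params_, b.params_, rtol=1e-8)

    def test_constant_outcome_raises_separation(self):
        x = np.linspace(-1, 1, 50)
        with pytest.raises(SeparationError):
            ClusterLogit().fit(x, np.ones(50))

    def test_perfectly_separated_data_raises(self):
        x = np.linspace(-2, 2, 80)
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            ClusterLogit().fit(x, y)

    def test_rank_deficiency_raises(self):
        x = np.ones(60)
        y = np.r_[np.zeros(30), np.ones(30)]
        with pytest.raises(ValueError, match="rank"):
            ClusterLogit().fit(x, y)

    def test_get_set_params_round_trip(self):
        est = ClusterLogit(max_iter=50)
        est.set_params(**est.get_params())
        assert est.get_params()["max_iter"] == 50


class TestWaldAndOR:
    def test_zero_coefficients_give_zero_statistic(self):
        x, y, g = _simulate_logit(300, (0.0, 0.5), seed=2, n_clusters=30)
        fit = fit_logit_cluster(y, x, g)
        fit.coefficients = np.zeros_like(fit.coefficients)
        res = wald(fit, [0, 1])
        assert res.statistic == 0 and res.p == 1

    def test_or_scaling_arithmetic(self):
        x, y, g = _simulate_logit(500, (-1.0, 0.05), seed=4, n_clusters=50)
        fit = fit_logit_cluster(y, x, g)
        fit.coefficients[1] = 0.05
        or10, _ = odds_ratio(fit, 1, unit_scale=10.0)
        assert or10 == pytest.approx(np.exp(0.5))

    def test_null_coefficient_ci_contains_one(self):
        x, y, g = _simulate_logit(800, (-0.5, 0.0), seed=6, n_clusters=40)
        fit = fit_logit_cluster(y, x, g)
        _, (lo, hi) = odds_ratio(fit, 1, unit_scale=1.0)
        assert lo < 1 < hi

    def test_spline_term_or_refused(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(50, 180, size=300)
        y = (rng.random(300) < 0.3).astype(float)
        fit = fit_rcs_logit(y, x, np.arange(300) // 5)
        with pytest.raises(ValueError, match="probability_curve"):
            odds_ratio(fit, 2)

    def test_known_or_coverage(self):
        """CI for a planted OR of 2.0 per unit must cover it in >= 90% of
        seeded replicates."""
        hits = 0
        reps = 60
        for seed in range(reps):
            x, y, g = _simulate_logit(600, (-0.8, np.log(2.0)), seed=seed,
                                      n_clusters=60)
            fit = fit_logit_cluster(y, x, g)
            _, (lo, hi) = odds_ratio(fit, 1)
            hits += lo <= 2.0 <= hi
        assert hits / reps >= 0.90


class TestProbabilityCurve:
    def test_band_contains_estimate_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(60, 180, size=400)
        y = (rng.random(400) < 0.25).astype(float)
        fit = fit_rcs_logit(y, x, np.arange(400) // 4)
        c = probability_curve(fit, np.linspace(x.min(), x.max(), 50))
        assert np.all(c.lower <= c.p) and np.all(c.p <= c.upper)
        assert np.all((c.p >= 0) & (c.p <= 1))
        assert not c.extrapolated.any()

    def test_intercept_only_curve_is_flat_at_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logit_cluster(y, None, np.arange(100) // 2)
        c = probability_curve(fit, np.linspace(0, 10, 5))
        assert c.p == pytest.approx(0.3)

    def test_extrapolation_flagged(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(100, 150, size=200)
        y = (rng.random(200) < 0.3).astype(float)
        fit = fit_rcs_logit(y, x, np.arange(200) // 4)
        c = probability_curve(fit, [90.0, 120.0, 160.0])
        assert c.extrapolated.tolist() == [True, False, True]

    def test_wald_detects_planted_inverted_u(self):
        """A strong inverted-U in the log-odds must give a non-linearity
        p-value below 0.01 at n = 500."""
        rng = np.random.default_rng(11)
        x = rng.uniform(50, 200, size=500)
        eta = -1.0 - ((x - 125) / 30.0) ** 2 / 2
        y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_rcs_logit(y, x, np.arange(500) // 5)
        assert wald_nonlinear(fit).p < 0.01
        assert wald_overall(fit).p < 0.01


class TestCohortFlow:
    def test_study_flow_percentages(self):
        f = cohort_flow(12803, 11648, 236, 2300, 2178, 771)
        assert f["liveborn"] == 11412
        assert (f["stabilized_pct"], f["suctioned_pct"], f["ventilated_pct"]) == (
            20.2, 19.1, 6.8,
        )

    def test_zero_stabilized(self):
        assert cohort_flow(100, 90, 10, 0, 0, 0)["stabilized_pct"] == 0.0

    def test_all_stabilized(self):
        assert cohort_flow(100, 90, 10, 80, 0, 0)["stabilized_pct"] == 100.0

    def test_no_liveborn_rejected(self):
        with pytest.raises(ValueError):
            cohort_flow(10, 5, 5, 0, 0, 0)

    def test_percent_formatter(self):
        assert percent(17, 135) == 12.6
        assert percent(11, 135) == 8.1
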