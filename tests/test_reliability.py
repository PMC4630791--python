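"""Reliability estimation, bootstrap, correlation comparison, moderators."""

import numpy as np
import pytest

from cognorm.reliability import (
    DegenerateVarianceError,
    bootstrap_reliability,
    engagement_variance_model,
    fisher_z_two_sample,
    grouped_reliability,
    pearson_fisher_ci,
    quartile_edges,
    reliability_estimate,
    sd_bin_edges,
)


class TestPearsonFisherCI:
    def test_perfect_linear_pairs(self):
        est = pearson_fisher_ci([1, 2, 3, 4], [2, 4, 6, 8])
        assert est.r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # cov = 1.6, sd_x = sd_y = sqrt(2) -> r = 0.8
        est = pearson_fisher_ci([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert est.r == pytest.approx(0.8, abs=1e-12)

    def test_null_interval_closed_form(self):
        # r = 0, n = 403: CI = tanh(±1.96/20) = ±0.0977
        x = np.arange(-201.0, 202.0)  # symmetric, n = 403
        y = x**2  # sum of x^3 is 0, so the sample correlation is exactly 0
        est = pearson_fisher_ci(x, y)
        assert est.r == pytest.approx(0.0, abs=1e-12)
        assert est.ci_low == pytest.approx(-0.0977, abs=1e-3)
        assert est.ci_high == pytest.approx(0.0977, abs=1e-3)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            pearson_fisher_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_analytic_interval_covers_truth_at_nominal_rate(self):
        rng = np.random.default_rng(0)
        rho, n, draws = 0.8, 100, 2000
        hits = 0
        for _ in range(draws):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            est = pearson_fisher_ci(x, y)
            hits += est.ci_low <= rho <= est.ci_high
        assert 0.93 <= hits / draws <= 0.97


class TestBootstrap:
    def test_perfectly_correlated_pairs(self):
        x = np.arange(10.0)
        boot = bootstrap_reliability(x, 2 * x + 1, n_iter=200, seed=1)
        assert boot.median == pytest.approx(1.0)
        assert boot.iqr == pytest.approx(0.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        a = bootstrap_reliability(x, y, n_iter=500, seed=11)
        b = bootstrap_reliability(x, y, n_iter=500, seed=11)
        assert (a.median, a.iqr, a.ci_low, a.ci_high) == (
            b.median,
            b.iqr,
            b.ci_low,
            b.ci_high,
        )

    def test_median_tracks_sample_correlation(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        y = 0.6 * x + 0.8 * rng.standard_normal(200)
        est = reliability_estimate(x, y, n_iter=2000, seed=4)
        boot_se = (est.bootstrap.ci_high - est.bootstrap.ci_low) / 3.92
        assert abs(est.bootstrap.median - est.r) <= 2.0 * boot_se

    def test_summary_mirrors_reporting_columns(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        est = reliability_estimate(x, y, n_iter=400, seed=6)
        b = est.bootstrap
        assert b.ci_low <= b.median <= b.ci_high
        assert b.iqr >= 0 and est.n_pairs == 60


class TestFisherZTwoSample:
    def test_equal_correlations_give_null(self):
        z, p = fisher_z_two_sample(0.5, 50, 0.5, 80)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_published_engaged_vs_non_engaged_comparison(self):
        # r = 0.846 (n=161) vs r = 0.836 (n=177)
        z, p = fisher_z_two_sample(0.846, 161, 0.836, 177)
        assert z == pytest.approx(0.32, abs=0.015)
        assert p > 0.7

    def test_closed_form_value(self):
        z, _ = fisher_z_two_sample(0.5, 103, 0.3, 103)
        assert z == pytest.approx(1.6955, abs=1e-3)

    def test_antisymmetry(self):
        z1, p1 = fisher_z_two_sample(0.7, 40, 0.4, 60)
        z2, p2 = fisher_z_two_sample(0.4, 60, 0.7, 40)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_two_sample(1.0, 50, 0.5, 50)
        with pytest.raises(ValueError):
            fisher_z_two_sample(0.5, 3, 0.5, 50)


class TestGroupedReliability:
    def test_single_group_equals_ungrouped(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(40)
        y = 0.7 * x + rng.standard_normal(40)
        grouped, _ = grouped_reliability(x, y, np.zeros(40), scheme="labels")
        plain = pearson_fisher_ci(x, y)
        assert grouped[0.0].r == plain.r
        assert grouped[0.0].ci_low == plain.ci_low

    def test_interval_bin_edges_reproduce_published_ranges(self):
        # mean 78.8, SD 19.86 -> integer edges 69 / 89 / 109, i.e. bins
        # 29-68, 69-88, 89-108, 109-235
        rng = np.random.default_rng(9)
        raw = rng.normal(78.8, 19.86, 4001)
        v = np.round(np.clip(raw, 29, 235))
        v = 78.8 + (v - v.mean()) * (19.86 / v.std(ddof=1))  # exact moments
        edges = sd_bin_edges(v)
        assert edges == [69.0, 89.0, 109.0]
        _, got = grouped_reliability(v, v + rng.standard_normal(v.size), v,
                                     scheme="sd_bins")
        assert got == edges

    def test_boundary_days_assign_downward(self):
        from cognorm.reliability import _bin_labels_from_edges

        x = np.array([68.0, 69.0, 88.0, 89.0, 108.0, 109.0])
        edges = [69.0, 89.0, 109.0]
        bins = _bin_labels_from_edges(x, edges, closed="left")
        assert list(bins) == [0, 1, 1, 2, 2, 3]
        # quartile convention is right-closed: the cut value stays below
        q = _bin_labels_from_edges(np.array([135.0, 136.0]), [135.0], closed="right")
        assert list(q) == [0, 1]

    def test_quartile_edges_are_right_closed_integer_cuts(self):
        v = np.arange(1.0, 101.0)
        assert quartile_edges(v) == [25.0, 50.0, 75.0]

    def test_two_groups_recover_their_generating_correlations(self):
        rng = np.random.default_rng(10)
        n = 3000
        out = {}
        for label, rho in (("a", 0.9), ("b", 0.5)):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            out[label] = (x, y)
        x = np.concatenate([out["a"][0], out["b"][0]])
        y = np.concatenate([out["a"][1], out["b"][1]])
        g = np.array(["a"] * n + ["b"] * n)
        est, _ = grouped_reliability(x, y, g, scheme="labels")
        for label, rho in (("a", 0.9), ("b", 0.5)):
            mc = 3.0 * (1 - rho**2) / np.sqrt(n)
            assert est[label].r == pytest.approx(rho, abs=mc)

    def test_small_groups_skipped(self):
        x = np.arange(10.0)
        y = x + 1
        g = np.array(["big"] * 8 + ["tiny"] * 2)
        est, _ = grouped_reliability(x, y, g, scheme="labels")
        assert "tiny" not in est and "big" in est


class TestEngagementVarianceModel:
    def test_identical_sessions_leave_no_residual_variance(self):
        rng = np.random.default_rng(12)
        s1 = rng.standard_normal(50)
        eng = rng.uniform(0, 100, 50)
        res = engagement_variance_model(s1, s1, eng)
        assert res.stage1.r_squared == pytest.approx(1.0)
        assert res.stage2.params["engagement"] == pytest.approx(0.0, abs=1e-12)

    def test_stage1_matches_normal_equations(self):
        rng = np.random.default_rng(13)
        s1 = rng.standard_normal(30)
        eng = rng.uniform(0, 10, 30)
        s2 = 1.0 + 0.5 * s1 + 0.1 * eng + 0.3 * rng.standard_normal(30)
        res = engagement_variance_model(s1, s2, eng)
        X = np.column_stack([np.ones(30), s1, eng])
        beta = np.linalg.solve(X.T @ X, X.T @ s2)
        assert res.stage1.params["const"] == pytest.approx(beta[0], abs=1e-10)
        assert res.stage1.params["score1"] == pytest.approx(beta[1], abs=1e-10)
        assert res.stage1.params["engagement"] == pytest.approx(beta[2], abs=1e-10)

    def test_constructed_heteroscedasticity_detected(self):
        rng = np.random.default_rng(14)
        n = 10_000
        s1 = rng.standard_normal(n)
        eng = rng.uniform(0, 1, n)
        noise_sd = 0.3 + 1.2 * eng
        s2 = 0.8 * s1 + noise_sd * rng.standard_normal(n)
        res = engagement_variance_model(s1, s2, eng)
        assert res.stage2.params["engagement"] > 0
        assert res.stage2.pvalues["engagement"] < 1e-6

    def test_homoscedastic_null_rarely_flags(self):
        flags = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 2000
            s1 = rng.standard_normal(n)
            eng = rng.uniform(0, 1, n)
            s2 = 0.8 * s1 + 0.6 * rng.standard_normal(n)
            res = engagement_variance_model(s1, s2, eng)
            flags += abs(res.stage2.tvalues["engagement"]) >= 1.96
        assert flags <= 2

    def test_collinear_predictors_rejected(self):
        s1 = np.arange(12.0)
        with pytest.raises(ValueError):
            engagement_variance_model(s1, s1 + 1, s1 * 2.0)
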