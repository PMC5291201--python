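"""Kernel-test core: weights, null model, quadratic form, oracles."""

import numpy as np
import pytest
from scipy import stats

from mqtlcollapse.skat import (
    WeightSpec,
    beta_weights,
    burden_test,
    fit_null,
    kernel_statistic,
    permutation_pvalue,
    quadform_pvalue,
    single_variant_regression,
    skat_test,
)


def rare_genotypes(rng, n, mafs):
    return (rng.binomial(1, mafs, (n, len(mafs))) + rng.binomial(1, mafs, (n, len(mafs)))).astype(float)


class TestBetaWeights:
    def test_closed_form_default(self):
        # Beta(1, 25) density at m is 25 (1-m)^24
        m = np.array([0.01, 0.03, 0.05])
        np.testing.assert_allclose(beta_weights(m), 25 * (1 - m) ** 24, rtol=1e-12)
        assert beta_weights(np.array([0.01]))[0] == pytest.approx(19.642, abs=1e-3)

    def test_flat_when_uniform(self):
        w = beta_weights(np.array([0.01, 0.2, 0.5]), WeightSpec(1, 1))
        np.testing.assert_allclose(w, 1.0)

    def test_monotone_decreasing_in_maf(self):
        w = beta_weights(np.array([0.01, 0.05]))
        assert w[0] > w[1]

    def test_rejects_out_of_range_maf(self):
        with pytest.raises(ValueError):
            beta_weights(np.array([0.0, 0.01]))
        with pytest.raises(ValueError):
            beta_weights(np.array([0.6]))

    def test_custom_override(self):
        w = beta_weights(np.array([0.01, 0.05]), WeightSpec(custom_weights=np.array([2.0, 3.0])))
        np.testing.assert_allclose(w, [2.0, 3.0])


class TestNullModel:
    def test_intercept_only_residuals_are_centered_y(self):
        rng = np.random.default_rng(0)
        y = 3.0 + rng.normal(size=50)
        null = fit_null(y)
        np.testing.assert_allclose(null.residuals, y - y.mean(), atol=1e-12)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=100)
        null = fit_null(y, X)
        for j in range(3):
            assert abs(null.residuals @ X[:, j]) < 1e-8 * 100

    def test_exact_linear_outcome_is_degenerate(self):
        X = np.linspace(0, 1, 30)[:, None]
        y = 2.0 + 3.0 * X[:, 0]
        with pytest.raises(ValueError, match="degenerate residual variance"):
            fit_null(y, X)

    def test_rank_deficiency_raises(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_null(rng.normal(size=40), np.column_stack([x, 2 * x]))


class TestQuadformPvalue:
    def test_one_df_tail(self):
        p, _ = quadform_pvalue(3.841459, np.array([1.0]))
        assert p == pytest.approx(0.05, abs=5e-5)

    def test_scale_invariance(self):
        p, _ = quadform_pvalue(7.682918, np.array([2.0]))
        assert p == pytest.approx(0.05, abs=5e-5)

    def test_two_df_tail(self):
        p, _ = quadform_pvalue(5.991465, np.array([1.0, 1.0]))
        assert p == pytest.approx(0.05, abs=5e-5)

    def test_against_monte_carlo_mixture(self):
        lam = np.array([3.0, 1.0, 0.5])
        q = 10.0
        p, method = quadform_pvalue(q, lam)
        assert method == "exact_quadform"
        rng = np.random.default_rng(12345)
        draws = (rng.chisquare(1, (10**6, 3)) * lam).sum(axis=1)
        p_mc = float(np.mean(draws >= q))
        se = np.sqrt(p_mc * (1 - p_mc) / 10**6)
        assert abs(p - p_mc) < 3 * se

    def test_monotone_through_method_crossover(self):
        # p must decrease monotonically as Q grows, including across the
        # switch from CF inversion to the moment-matched far-tail route
        lam = np.array([2.0, 1.0, 0.3, 0.3])
        qs = np.linspace(5, 400, 120)
        ps = [quadform_pvalue(float(q), lam)[0] for q in qs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        methods = {quadform_pvalue(float(q), lam)[1] for q in qs}
        assert methods == {"exact_quadform", "moment_matched"}

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            quadform_pvalue(1.0, np.array([]))


class TestKernelStatistic:
    def test_all_zero_genotypes_fail(self):
        null = fit_null(np.random.default_rng(0).normal(size=30))
        with pytest.raises(ValueError, match="no testable variants"):
            kernel_statistic(null, np.zeros((30, 3)), np.ones(3))

    def test_single_variant_equals_score_test(self):
        # 1-df limit: kernel p must match the closed-form score test
        rng = np.random.default_rng(3)
        n = 150
        g = rare_genotypes(rng, n, [0.2])[:, 0]
        X = rng.normal(size=(n, 2))
        y = 0.3 * g + rng.normal(size=n)
        null = fit_null(y, X)
        res = skat_test(y, X, g[:, None], WeightSpec(custom_weights=np.array([1.0])))
        g_perp = null.project((g - g.mean())[:, None])[:, 0]
        t_score = (g_perp @ null.residuals) ** 2 / (null.sigma2 * (g_perp @ g_perp))
        p_score = stats.chi2.sf(t_score, 1)
        assert abs(res.p_value - p_score) < 1e-6

    def test_duplicated_column_tolerated(self):
        rng = np.random.default_rng(4)
        g = rare_genotypes(rng, 100, [0.1])[:, 0]
        y = rng.normal(size=100)
        res = skat_test(y, None, np.column_stack([g, g]))
        assert 0 < res.p_value <= 1

    def test_invariant_to_sample_reordering(self):
        rng = np.random.default_rng(5)
        n = 120
        G = rare_genotypes(rng, n, [0.05, 0.1, 0.2])
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        perm = rng.permutation(n)
        a = skat_test(y, X, G)
        b = skat_test(y[perm], X[perm], G[perm])
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_invariant_to_allele_recoding(self):
        # flipping minor/major coding (g -> 2-g) with folded-MAF weights
        rng = np.random.default_rng(6)
        n = 200
        G = rare_genotypes(rng, n, [0.1, 0.3])
        y = rng.normal(size=n)
        mafs = np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2)
        a = skat_test(y, None, G, mafs=mafs)
        G2 = G.copy()
        G2[:, 0] = 2 - G2[:, 0]
        b = skat_test(y, None, G2, mafs=mafs)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)


class TestSkatTest:
    def test_mixed_signs_beat_burden(self):
        # sign cancellation: the variance-component test keeps power where
        # the weighted sum test loses it
        rng = np.random.default_rng(7)
        n = 500
        G = rare_genotypes(rng, n, [0.05] * 6)
        beta = np.array([0.5, -0.5, 0.5, -0.5, 0.5, -0.5])
        y = G @ beta + rng.normal(size=n)
        p_kernel = skat_test(y, None, G).p_value
        p_burden = burden_test(y, None, G)["p"]
        assert p_kernel < p_burden

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        G = rare_genotypes(rng, 80, [0.1, 0.2])
        y = rng.normal(size=80)
        assert skat_test(y, None, G).p_value == skat_test(y, None, G).p_value

    def test_effect_scaling_does_not_increase_median_p(self):
        # amplifying every |beta| (same noise draw) must not weaken evidence
        rng = np.random.default_rng(9)
        n = 300
        medians = []
        for scale in (0.0, 0.3, 0.8):
            ps = []
            for rep in range(40):
                r = np.random.default_rng(1000 + rep)
                G = rare_genotypes(r, n, [0.05] * 4)
                eps = r.normal(size=n)
                beta = scale * np.array([1.0, -1.0, 1.0, -1.0])
                ps.append(skat_test(G @ beta + eps, None, G).p_value)
            medians.append(np.median(ps))
        assert medians[0] >= medians[1] >= medians[2]


class TestPermutationOracle:
    def test_extreme_statistic_hits_lower_bound(self):
        rng = np.random.default_rng(10)
        n = 200
        G = rare_genotypes(rng, n, [0.2, 0.3])
        y = 3.0 * G[:, 0] + 0.01 * rng.normal(size=n)
        assert permutation_pvalue(y, None, G, n_perm=100, seed=0) == pytest.approx(1 / 101)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(11)
        G = rare_genotypes(rng, 150, [0.1, 0.2])
        y = rng.normal(size=150)
        a = permutation_pvalue(y, None, G, n_perm=199, seed=5)
        b = permutation_pvalue(y, None, G, n_perm=199, seed=5)
        assert a == b

    def test_null_permutation_p_roughly_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for rep in range(200):
            r = np.random.default_rng(2000 + rep)
            G = rare_genotypes(r, 100, [0.2, 0.3])
            y = r.normal(size=100)
            ps.append(permutation_pvalue(y, None, G, n_perm=199, seed=rep))
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_agrees_with_analytic_p(self):
        # smaller-scale version of the oracle-equivalence property
        rng = np.random.default_rng(13)
        checked = 0
        for i in range(20):
            n, p = 200, int(rng.integers(2, 7))
            G = rare_genotypes(rng, n, rng.uniform(0.05, 0.25, p))
            X = rng.normal(size=(n, 1))
            beta = rng.normal(0, 0.12, p) * rng.integers(0, 2)
            y = 0.2 * X[:, 0] + G @ beta + rng.normal(size=n)
            res = skat_test(y, X, G)
            if not 0.001 <= res.p_value <= 0.5:
                continue
            p_perm = permutation_pvalue(y, X, G, n_perm=20_000, seed=100 + i)
            se = np.sqrt(res.p_value * (1 - res.p_value) / 20_000)
            se_log = se / (res.p_value * np.log(10))
            assert abs(np.log10(res.p_value) - np.log10(p_perm)) < 3 * se_log
            checked += 1
        assert checked >= 5


class TestSingleVariantRegression:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(14)
        g = rare_genotypes(rng, 20, [0.4])[:, 0]
        est = single_variant_regression(2.0 * g + 1e-10 * rng.normal(size=20), None, g)
        assert est["beta"] == pytest.approx(2.0, abs=1e-6)
        assert est["p"] < 1e-50

    def test_null_p_uniform(self):
        rng = np.random.default_rng(15)
        ps = []
        for _ in range(500):
            g = rare_genotypes(rng, 60, [0.3])[:, 0]
            ps.append(single_variant_regression(rng.normal(size=60), None, g)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_collinear_covariate_raises(self):
        rng = np.random.default_rng(16)
        g = rare_genotypes(rng, 50, [0.3])[:, 0]
        with pytest.raises(ValueError, match="collinear"):
            single_variant_regression(rng.normal(size=50), g[:, None], g)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            single_variant_regression(np.ones(10), None, np.zeros(10))
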