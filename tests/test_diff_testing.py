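import numpy as np
import pytest
from scipy import stats

from hicdelta.diff_testing import (bh_adjust, design_matrix, estimate_dispersion_trend,
                                   fit_nb_glm, nb_deviance, ql_dispersions, ql_f_test)
from hicdelta.simhic import SimParams, simulate_counts


def _nb_counts(rng, mu, phi, shape):
    if phi == 0:
        return rng.poisson(mu, shape).astype(float)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), shape).astype(float)


class TestDesignMatrix:
    def test_two_group_one_hot_with_intercept(self):
        X, labels = design_matrix(["a", "a", "b", "b"])
        assert X.tolist() == [[1, 0], [1, 0], [1, 1], [1, 1]]
        assert labels == ["intercept", "b_vs_a"]

    def test_single_group_is_intercept_only(self):
        X, labels = design_matrix(["a", "a", "a"])
        assert X.shape == (3, 1) and labels == ["intercept"]


class TestFitNbGlm:
    def test_intercept_only_saturated_mean(self):
        fit = fit_nb_glm(np.array([[6.0, 6.0]]), np.ones((2, 1)), 0.0, 0.0)
        assert fit.coef[0, 0] == pytest.approx(np.log(6.0), abs=1e-8)
        assert fit.deviance[0] == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only_mean_solves_score_equation_any_phi(self):
        for phi in (0.0, 0.1, 1.0):
            fit = fit_nb_glm(np.array([[2.0, 4.0]]), np.ones((2, 1)), 0.0, phi)
            assert fit.coef[0, 0] == pytest.approx(np.log(3.0), abs=1e-7)

    def test_matches_statsmodels_poisson(self):
        import statsmodels.api as smapi

        rng = np.random.default_rng(0)
        X, _ = design_matrix(["a", "a", "b", "b", "b"])
        y = rng.poisson(20, (8, 5)).astype(float)
        off = rng.normal(0, 0.2, 5)
        mine = fit_nb_glm(y, X, off, 0.0)
        for i in range(len(y)):
            ref = smapi.GLM(y[i], X, family=smapi.families.Poisson(), offset=off).fit()
            assert np.allclose(mine.coef[i], ref.params, atol=1e-6)
            assert mine.deviance[i] == pytest.approx(ref.deviance, abs=1e-6)

    def test_library_offset_constant_shifts_fitted_means(self):
        X, _ = design_matrix(["a", "a", "b", "b"])
        y = np.array([[10.0, 12.0, 30.0, 28.0]])
        base = fit_nb_glm(y, X, 0.0, 0.05)
        shifted = fit_nb_glm(y, X, np.array([0.7, 0.7, 0.7, 0.7]), 0.05)
        assert np.allclose(shifted.mu, base.mu)  # absorbed by the intercept
        assert shifted.coef[0, 0] == pytest.approx(base.coef[0, 0] - 0.7, abs=1e-6)


class TestDispersionTrend:
    def test_poisson_data_has_negligible_dispersion(self):
        rng = np.random.default_rng(1)
        X, _ = design_matrix(["a", "a", "b", "b"])
        mu = np.exp(rng.uniform(np.log(20), np.log(500), 4000))
        y = _nb_counts(rng, mu[:, None], 0.0, (4000, 4)[::-1]).T if False else \
            rng.poisson(np.tile(mu[:, None], (1, 4)))
        d = estimate_dispersion_trend(y.astype(float), X, 0.0, abundance=np.log2(mu))
        assert d.trended.max() <= 0.005

    def test_constant_nb_dispersion_recovered(self):
        rng = np.random.default_rng(2)
        X, _ = design_matrix(["a", "a", "b", "b"])
        mu = np.exp(rng.uniform(np.log(20), np.log(500), 8000))
        y = _nb_counts(rng, np.tile(mu[:, None], (1, 4)), 0.05, (8000, 4))
        d = estimate_dispersion_trend(y, X, 0.0, abundance=np.log2(mu))
        mid = (np.log2(mu) > np.quantile(np.log2(mu), 0.25)) & \
              (np.log2(mu) < np.quantile(np.log2(mu), 0.75))
        assert 0.04 < d.trended[mid].mean() < 0.06

    def test_decreasing_dispersion_shape_recovered(self):
        rng = np.random.default_rng(3)
        X, _ = design_matrix(["a", "a", "b", "b"])
        mu = np.exp(rng.uniform(np.log(20), np.log(2000), 8000))
        a = np.log2(mu)
        phi_true = 0.2 * (a.max() - a) / np.ptp(a) + 0.02
        y = np.column_stack([_nb_counts(rng, mu, p, (4,)) for mu, p in zip(mu, phi_true)]).T
        d = estimate_dispersion_trend(y, X, 0.0, abundance=a)
        lo = d.trended[a < np.quantile(a, 0.2)].mean()
        hi = d.trended[a > np.quantile(a, 0.8)].mean()
        assert lo > hi
        knots = d._knots_y
        assert knots[0] > knots[-1]

    def test_no_replication_rejected(self):
        X, _ = design_matrix(["a", "b"])
        with pytest.raises(ValueError):
            estimate_dispersion_trend(np.ones((10, 2)), X, 0.0)


class TestQlDispersions:
    def _fit(self, seed=4, n=4000, sigma=1.0):
        rng = np.random.default_rng(seed)
        X, _ = design_matrix(["a", "a", "b", "b"])
        mu = np.exp(rng.uniform(np.log(20), np.log(500), n))
        y = _nb_counts(rng, np.tile(mu[:, None], (1, 4)), 0.05, (n, 4))
        fit = fit_nb_glm(y, X, 0.0, 0.05)
        return fit, np.log2(mu)

    def test_identical_raw_values_give_infinite_prior(self):
        X, _ = design_matrix(["a", "a", "b", "b"])
        fit = fit_nb_glm(np.tile([10.0, 10, 20, 20], (50, 1)), X, 0.0, 0.0)
        ql = ql_dispersions(fit, np.full(50, 5.0))
        assert np.isinf(ql.prior_df)

    def test_squeezed_lies_between_raw_and_trend(self):
        fit, a = self._fit()
        ql = ql_dispersions(fit, a)
        lo = np.minimum(ql.raw, ql.trend) - 1e-9
        hi = np.maximum(ql.raw, ql.trend) + 1e-9
        assert np.all((ql.squeezed >= lo) & (ql.squeezed <= hi))

    def test_mean_squeezed_near_unity_under_nb_truth(self):
        fit, a = self._fit(n=10000)
        ql = ql_dispersions(fit, a)
        assert 0.9 < ql.squeezed.mean() < 1.1

    def test_robust_mode_resists_outliers(self):
        fit, a = self._fit()
        fit.deviance[:40] *= 30  # a few wildly variable bin pairs
        d0_rob = ql_dispersions(fit, a, robust=True).prior_df
        d0_plain = ql_dispersions(fit, a, robust=False).prior_df
        assert d0_rob >= d0_plain


class TestQlFTest:
    def test_identical_counts_give_zero_logfc_and_p_near_one(self):
        X, _ = design_matrix(["a", "a", "b", "b"])
        y = np.tile([15.0, 15, 15, 15], (20, 1))
        y[1:] += np.arange(19)[:, None]  # spread so the EB moments exist
        fit = fit_nb_glm(y, X, 0.0, 0.05)
        ql = ql_dispersions(fit, np.log2(y.mean(axis=1)))
        res = ql_f_test(fit, ql, [0.0, 1.0])
        assert res["logFC"][0] == pytest.approx(0.0, abs=1e-8)
        assert res["pvalue"][0] > 0.99

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        X, _ = design_matrix(["a", "a", "b", "b"])
        mu = np.exp(rng.uniform(np.log(20), np.log(500), 10000))
        y = _nb_counts(rng, np.tile(mu[:, None], (1, 4)), 0.05, (10000, 4))
        a = np.log2(mu)
        d = estimate_dispersion_trend(y, X, 0.0, abundance=a)
        fit = fit_nb_glm(y, X, 0.0, d.trended)
        ql = ql_dispersions(fit, a)
        res = ql_f_test(fit, ql, [0.0, 1.0])
        assert stats.kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_large_count_limit_matches_z_test(self):
        rng = np.random.default_rng(6)
        X, _ = design_matrix(["a", "a", "b", "b"])
        mu = np.full((4000, 4), 5000.0)
        y = rng.poisson(mu).astype(float)
        fit = fit_nb_glm(y, X, 0.0, 0.0)
        ql = ql_dispersions(fit, np.log2(y.mean(axis=1)))
        res = ql_f_test(fit, ql, [0.0, 1.0])
        # Wald z-test on log means with Poisson variance
        m1, m2 = y[:, :2].mean(axis=1), y[:, 2:].mean(axis=1)
        se = np.sqrt(1 / (2 * m1) + 1 / (2 * m2))
        z = (np.log(m2) - np.log(m1)) / se
        pz = 2 * stats.norm.sf(np.abs(z))
        mask = pz > 1e-6
        assert np.median(np.abs(res["pvalue"][mask] - pz[mask]) / pz[mask]) < 0.1

    def test_contrast_outside_design_rejected(self):
        X, _ = design_matrix(["a", "a", "b", "b"])
        y = np.tile([5.0, 6, 7, 8], (30, 1))
        fit = fit_nb_glm(y, X, 0.0, 0.0)
        ql = ql_dispersions(fit, np.log2(y.mean(axis=1)))
        with pytest.raises(ValueError):
            ql_f_test(fit, ql, [0.0, 1.0, 1.0])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.042]).tolist() == [0.042]

    def test_step_up_by_hand(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_matches_independent_step_up(self):
        def reference_bh(p):
            p = np.asarray(p, float)
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(7)
        for _ in range(25):
            p = rng.uniform(0, 1, rng.integers(1, 60))
            assert np.allclose(bh_adjust(p), reference_bh(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestOffsetInvariance:
    def test_shared_constant_offset_leaves_f_statistics_unchanged(self):
        """A per-library constant added to every offset is absorbed by the
        intercept/group coefficients and cannot change the contrast test."""
        cm, _ = simulate_counts(SimParams(n_bins=(20, 20)), seed=8)
        X, _ = design_matrix(["a", "a", "b", "b"])
        y = cm.counts.astype(float)
        a = np.log2(y.mean(axis=1) + 0.5)
        base_off = np.log(cm.lib_sizes)
        f1 = fit_nb_glm(y, X, base_off, 0.05)
        q1 = ql_dispersions(f1, a)
        r1 = ql_f_test(f1, q1, [0.0, 1.0])
        # same constant for every library: absorbed by the intercept
        f2 = fit_nb_glm(y, X, base_off + 0.7, 0.05)
        q2 = ql_dispersions(f2, a)
        r2 = ql_f_test(f2, q2, [0.0, 1.0])
        assert np.allclose(r1["F"], r2["F"], rtol=1e-5, atol=1e-7)
        assert np.allclose(f2.coef[:, 0], f1.coef[:, 0] - 0.7, atol=1e-6)
        # a per-group constant is absorbed by the group coefficient and
        # shifts every logFC by exactly that amount
        shift = np.array([0.3, 0.3, -0.2, -0.2])
        f3 = fit_nb_glm(y, X, base_off + shift, 0.05)
        assert np.allclose(f3.coef[:, 1], f1.coef[:, 1] + 0.5, atol=1e-6)
        assert np.allclose(f3.mu, f1.mu, rtol=1e-6)
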