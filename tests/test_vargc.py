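"""VAR estimation and Granger causality: oracles and properties.

Independent oracles: statsmodels' OLS-based VAR estimator for coefficient
cross-checks, closed-form AR(1)/white-noise covariances, and the analytic
GC of known VAR models from their exact (Lyapunov) covariances.
"""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ifgc import fixtures, vargc
from ifgc.vargc import (EstimationError, TimeSeriesSet, conditional_gc_matrix,
                        demean, estimate_covariances, fit_var_yule_walker,
                        gc_significance_threshold, pairwise_gc,
                        select_order_bic)


class TestDemean:
    def test_removes_means_preserves_variance(self, rng):
        X = rng.normal([3.0, -1.0], [2.0, 0.5], size=(4000, 2))
        out = demean(X)
        np.testing.assert_allclose(out.data.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.data.var(axis=0), X.var(axis=0),
                                   rtol=1e-12)

    @given(shift=st.floats(-50, 50))
    def test_idempotent_up_to_shift(self, shift):
        base = np.sin(np.arange(200.0))[:, None]
        once = demean(base + shift).data
        twice = demean(once).data
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_constant_channel_flagged(self):
        X = np.column_stack([np.ones(100), np.arange(100.0)])
        with pytest.raises(EstimationError, match="constant"):
            demean(X)


class TestCovariances:
    def test_white_noise_lags_vanish(self, rng):
        T = 40_000
        X = rng.standard_normal((T, 2))
        G = estimate_covariances(demean(X), 5)
        assert np.abs(G[1:]).max() < 3.5 / np.sqrt(T)
        np.testing.assert_allclose(G[0], G[0].T)

    def test_ar1_ratio_recovers_coefficient(self, rng):
        phi = 0.7
        T = 100_000
        e = rng.standard_normal(T + 100)
        x = np.zeros(T + 100)
        for t in range(1, T + 100):
            x[t] = phi * x[t - 1] + e[t]
        G = estimate_covariances(demean(x[100:, None]), 1)
        assert G[1][0, 0] / G[0][0, 0] == pytest.approx(phi, abs=0.01)

    def test_lag_zero_of_standardized_is_identity(self, rng):
        X = rng.standard_normal((20_000, 3))
        X /= X.std(axis=0)
        G = estimate_covariances(demean(X), 0)
        np.testing.assert_allclose(np.diag(G[0]), 1.0, atol=0.02)

    def test_max_lag_bound(self):
        with pytest.raises(EstimationError):
            estimate_covariances(np.zeros((10, 1)) + np.arange(10)[:, None], 10)


class TestYuleWalker:
    def test_recovers_var2_coefficients(self):
        fx = fixtures.generate_var_fixture(m=2, p=2, seed=3)
        X = fixtures.simulate_var(fx, 100_000, seed=4)
        fit = fit_var_yule_walker(X, 2)
        # asymptotic coefficient SEs are O(1/sqrt(T)); allow 4x margin
        assert np.abs(fit.coefficients - fx.coefficients).max() < 4.5 / np.sqrt(1e5)
        assert np.allclose(fit.noise_cov, fit.noise_cov.T)

    def test_white_noise_coefficients_near_zero(self, rng):
        X = rng.standard_normal((50_000, 2))
        fit = fit_var_yule_walker(X, 3)
        assert np.abs(fit.coefficients).max() < 4 / np.sqrt(50_000)

    def test_matches_ols_oracle(self):
        # statsmodels fits the VAR by least squares; Yule-Walker must agree
        # up to edge effects on a moderately long sample
        sm = pytest.importorskip("statsmodels.tsa.api")
        fx = fixtures.generate_var_fixture(m=2, p=2, seed=8)
        X = fixtures.simulate_var(fx, 20_000, seed=9)
        fit = fit_var_yule_walker(X, 2)
        res = sm.VAR(X - X.mean(axis=0)).fit(maxlags=2, trend="n")
        ols = np.stack([res.coefs[u] for u in range(2)])
        assert np.abs(fit.coefficients - ols).max() < 5e-2

    def test_residual_whiteness_ljung_box(self):
        smd = pytest.importorskip("statsmodels.stats.diagnostic")
        fx = fixtures.generate_var_fixture(m=2, p=2, seed=5)
        X = fixtures.simulate_var(fx, 50_000, seed=6)
        fit = fit_var_yule_walker(X, 2)
        for ch in range(2):
            lb = smd.acorr_ljungbox(fit.residuals[:, ch], lags=[10])
            assert lb["lb_pvalue"].iloc[0] > 0.01

    def test_exclude_channel(self):
        fx = fixtures.generate_var_fixture(m=3, p=1, seed=2)
        X = fixtures.simulate_var(fx, 5_000, seed=2)
        fit = fit_var_yule_walker(X, 2, exclude=1)
        assert fit.coefficients.shape == (2, 2, 2)
        assert fit.excluded_channel == 1


class TestOrderSelection:
    def test_recovers_var3_order(self):
        fx = fixtures.generate_var_fixture(m=2, p=3, seed=12)
        X = fixtures.simulate_var(fx, 100_000, seed=13)
        p_star, curve = select_order_bic(X, 8)
        assert p_star == 3
        assert np.argmin(curve) + 1 == p_star

    def test_white_noise_selects_order_one(self, rng):
        X = rng.standard_normal((30_000, 2))
        p_star, _ = select_order_bic(X, 6)
        assert p_star == 1
        fit = fit_var_yule_walker(X, p_star)
        assert np.abs(fit.coefficients).max() < 4 / np.sqrt(30_000)


class TestPairwiseGc:
    def test_independent_channels_below_threshold(self, rng):
        T, p = 20_000, 4
        x, y = rng.standard_normal((2, T))
        F_yx, F_xy = pairwise_gc(x, y, p)
        thr = stats.chi2.ppf(0.999, p) / T
        assert F_yx < thr and F_xy < thr

    def test_pure_delay_is_unidirectional(self, rng):
        y = rng.standard_normal(50_000)
        x = np.roll(y, 1)  # x_t = y_{t-1}
        F_yx, F_xy = pairwise_gc(x[1:], y[1:], 2)
        assert F_yx > 1.0
        assert F_xy < 50 * 2 / 50_000

    def test_matches_analytic_gc_of_known_model(self):
        pattern = np.array([[0, 1], [0, 0]])  # coupling 1 -> 2 only
        fx = fixtures.generate_var_fixture(m=2, p=2, seed=21,
                                           coupling_pattern=pattern)
        X = fixtures.simulate_var(fx, 100_000, seed=22)
        F_yx, F_xy = pairwise_gc(X[:, 0], X[:, 1], 2)
        # estimated [1->2] close to analytic; reverse consistent with zero
        se = vargc.gc_standard_error(fx.analytic_gc[0, 1], 2, 100_000)
        assert abs(F_xy - fx.analytic_gc[0, 1]) < 3 * se
        assert fx.analytic_gc[1, 0] == 0.0
        assert F_yx < stats.chi2.ppf(0.999, 2) / 100_000


class TestConditionalGc:
    def test_three_independent_channels_null(self, rng):
        X = rng.standard_normal((20_000, 3))
        gc, _ = conditional_gc_matrix(X, order=3)
        thr = gc_significance_threshold(gc, alpha=0.001)
        assert gc.offdiag_values().max() < thr * 3

    def test_var_chain_spurious_bivariate_removed_by_conditioning(self):
        # chain 1 -> 2 -> 3: the bivariate (1,3) analysis sees an indirect
        # edge; conditioning on channel 2 removes it
        A = np.zeros((1, 3, 3))
        A[0] = [[0.6, 0, 0], [0.6, 0.5, 0], [0, 0.6, 0.4]]
        Sigma = np.eye(3)
        X = fixtures.simulate_var(
            fixtures.VarFixture(3, 1, A, Sigma, np.zeros((3, 3))),
            200_000, seed=31)
        T = X.shape[0]
        F13_biv, _ = pairwise_gc(X[:, 2], X[:, 0], 2)
        thr_biv = stats.chi2.ppf(0.99, 2) / T
        assert F13_biv > 5 * thr_biv
        gc, _ = conditional_gc_matrix(X, order=2)
        thr = gc_significance_threshold(gc, alpha=0.01)
        assert gc.values[0, 2] < thr          # indirect edge removed
        assert gc.values[0, 1] > thr and gc.values[1, 2] > thr

    def test_diagonal_zero_and_nonnegative(self, rng):
        X = rng.standard_normal((5_000, 3))
        gc, _ = conditional_gc_matrix(X, order=2)
        assert np.all(np.diag(gc.values) == 0)
        assert np.all(gc.values >= 0)

    def test_permutation_equivariance(self, rng):
        fx = fixtures.generate_var_fixture(m=3, p=1, seed=14)
        X = fixtures.simulate_var(fx, 30_000, seed=15)
        perm = [2, 0, 1]
        gc_a, _ = conditional_gc_matrix(X, order=1)
        gc_b, _ = conditional_gc_matrix(X[:, perm], order=1)
        np.testing.assert_allclose(gc_b.values,
                                   gc_a.values[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_estimates_converge_to_analytic_conditional_gc(self):
        fx = fixtures.generate_var_fixture(m=3, p=2, seed=40)
        X = fixtures.simulate_var(fx, 100_000, seed=41)
        gc, _ = conditional_gc_matrix(X, order=2)
        for j in range(3):
            for i in range(3):
                if i == j:
                    continue
                se = vargc.gc_standard_error(fx.analytic_gc[j, i], 2, 100_000)
                assert abs(gc.values[j, i] - fx.analytic_gc[j, i]) < 3 * se


class TestSignificanceThreshold:
    def test_limits_and_monotonicity(self, rng):
        X = rng.standard_normal((1_000, 2))
        gc, _ = conditional_gc_matrix(X, order=2)
        t1 = gc_significance_threshold(gc, 0.999999)
        assert t1 < 1e-8
        gc_long = vargc.GcMatrix(values=gc.values, order=2, n_samples=10_000)
        assert (gc_significance_threshold(gc_long, 0.01)
                < gc_significance_threshold(gc, 0.01))
        with pytest.raises(EstimationError):
            gc_significance_threshold(gc, 1.5)

    def test_bonferroni_is_stricter(self, rng):
        X = rng.standard_normal((1_000, 4))
        gc, _ = conditional_gc_matrix(X, order=1)
        assert (gc_significance_threshold(gc, 0.01, bonferroni=True)
                > gc_significance_threshold(gc, 0.01))


class TestFilterInvariance:
    def test_causal_lowpass_preserves_gc(self, two_neuron_record):
        from scipy import signal
        X = two_neuron_record.voltages
        Xf = signal.lfilter([1.0], [1.0, -0.4], X, axis=0)
        g0, _ = conditional_gc_matrix(X, order=8)
        g1, _ = conditional_gc_matrix(Xf, order=8)
        off = ~np.eye(2, dtype=bool)
        # changes are far below the estimates' own sampling error
        se = np.array([vargc.gc_standard_error(f, 8, X.shape[0])
                       for f in g0.values[off]])
        assert np.all(np.abs(g0.values - g1.values)[off] < se)
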