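"""Loss, gradient, base-learners and node-wise boosting."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import lsq_linear

from prtrees.boost import (
    BoostConfig,
    _difference_penalty,
    _penalty_weight,
    boost_node,
    cloglog_link,
    cloglog_response,
    compute_offset,
    fit_linear_baselearner,
    fit_monotone_time_baselearner,
    loss,
    negative_gradient,
    root_offset,
)
from prtrees.pseudo import InvalidInputError


class TestLinkAndLoss:
    def test_response_at_zero_and_limits(self):
        assert cloglog_response(0.0) == pytest.approx(1 - np.exp(-1))
        assert cloglog_response(800.0) == pytest.approx(0.0, abs=1e-12)
        assert cloglog_response(-800.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("s", [0.1, 0.5, 0.9])
    def test_link_inverse_identity(self, s):
        assert cloglog_response(cloglog_link(s)) == pytest.approx(s, abs=1e-12)

    def test_response_strictly_decreasing(self):
        # strict within the range where h is representable away from 0/1
        f = np.linspace(-3, 5, 101)
        assert np.all(np.diff(cloglog_response(f)) < 0)

    def test_loss_values(self):
        assert loss(cloglog_response(0.7), 0.7) == pytest.approx(0.0)
        assert loss(1.0, 0.0) == pytest.approx((1 - (1 - np.exp(-1))) ** 2)
        assert np.all(loss(np.array([-0.2, 0.3, 1.4]), np.array([1.0, -2.0, 0.5])) >= 0)


class TestNegativeGradient:
    def test_zero_at_fit(self):
        assert negative_gradient(cloglog_response(0.3), 0.3) == pytest.approx(0.0, abs=1e-14)

    def test_matches_numeric_differentiation(self, rng):
        theta = rng.uniform(-0.5, 1.5, 500)
        f = rng.uniform(-6, 6, 500)
        eps = 1e-6
        numeric = -(loss(theta, f + eps) - loss(theta, f - eps)) / (2 * eps)
        np.testing.assert_allclose(negative_gradient(theta, f), numeric, atol=1e-6)

    def test_guarded_for_extreme_predictors(self):
        assert negative_gradient(0.5, 50.0) == pytest.approx(0.0, abs=1e-12)
        assert negative_gradient(0.5, -50.0) == pytest.approx(0.0, abs=1e-12)
        assert np.isfinite(negative_gradient(0.5, -1e6))


class TestLinearBaseLearner:
    def test_exact_fit(self):
        x = np.array([1.0, -2.0, 0.5, 3.0])
        slope, fitted, rss = fit_linear_baselearner(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert rss == pytest.approx(0.0, abs=1e-20)

    def test_orthogonal_target(self, rng):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        u = np.array([1.0, 1.0, -1.0, -1.0])
        slope, _, rss = fit_linear_baselearner(x, u)
        assert slope == pytest.approx(0.0)
        assert rss == pytest.approx(u @ u)

    def test_formula_on_random_input(self, rng):
        x, u = rng.normal(size=10), rng.normal(size=10)
        slope, _, _ = fit_linear_baselearner(x, u)
        assert slope == pytest.approx((x @ u) / (x @ x))

    def test_constant_covariate_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_linear_baselearner(np.zeros(5), np.ones(5))


class TestMonotoneTimeLearner:
    grid = np.array([0.5, 1.0, 2.0, 3.5, 5.0])

    def test_interpolates_increasing_means_without_penalty(self, rng):
        kidx = np.repeat(np.arange(5), 8)
        t = self.grid[kidx]
        means = np.array([-1.0, -0.3, 0.2, 0.8, 1.5])
        u = means[kidx]
        a, fitted, rss = fit_monotone_time_baselearner(t, u, self.grid, df_target=5.0)
        np.testing.assert_allclose(a, means, atol=1e-8)
        assert rss == pytest.approx(0.0, abs=1e-12)

    def test_decreasing_target_clamped_to_constant(self, rng):
        kidx = np.repeat(np.arange(5), 4)
        u = -self.grid[kidx]
        a, _, _ = fit_monotone_time_baselearner(self.grid[kidx], u, self.grid)
        assert np.all(np.diff(a) >= -1e-9)
        assert np.ptp(a) < 1e-6  # essentially constant

    def test_matches_quadratic_program_oracle(self, rng):
        for _ in range(25):
            kidx = rng.integers(0, 5, 40)
            u = rng.normal(size=40)
            df = float(rng.uniform(2.5, 5.0))
            a, _, _ = fit_monotone_time_baselearner(self.grid[kidx], u, self.grid, df_target=df)
            K = 5
            W = np.bincount(kidx, minlength=K).astype(float)
            P = _difference_penalty(K, 2)
            lam = _penalty_weight(np.maximum(W, 1e-6), P, df)
            ubar = np.bincount(kidx, weights=u, minlength=K) / np.maximum(W, 1e-12)
            L = np.tril(np.ones((K, K)))
            D2 = np.diff(np.diff(np.eye(K), axis=0), axis=0)
            A = np.vstack([np.diag(np.sqrt(W)) @ L, np.sqrt(lam) * D2 @ L])
            b = np.concatenate([np.sqrt(W) * ubar, np.zeros(K - 2)])
            sol = lsq_linear(
                A, b, bounds=(np.r_[-np.inf, np.zeros(K - 1)], np.full(K, np.inf)), tol=1e-14
            )
            np.testing.assert_allclose(a, L @ sol.x, atol=1e-6)

    def test_same_time_same_fitted_value(self, rng):
        kidx = rng.integers(0, 5, 60)
        u = rng.normal(size=60)
        a, fitted, _ = fit_monotone_time_baselearner(self.grid[kidx], u, self.grid)
        np.testing.assert_array_equal(fitted, a[kidx])


def make_table(rng, n=40, K=4, p=2, signal=None):
    grid = np.linspace(1.0, 4.0, K)
    X = rng.normal(size=(n, p))
    # survival-like outcome: nonincreasing in time per individual on average
    theta = np.sort(rng.uniform(0, 1, (n, K)), axis=1)[:, ::-1].copy()
    if signal is not None:
        theta = np.clip(theta + signal * X[:, [0]] * 0.5, -0.3, 1.3)
    rows = {
        "id": np.repeat(np.arange(n), K),
        "time": np.tile(grid, n),
        "pseudo": theta.reshape(-1),
        "x0": 1.0,
    }
    for j in range(p):
        rows[f"x{j + 1}"] = np.repeat(X[:, j], K)
    return pd.DataFrame(rows), grid, theta


class TestBoostNode:
    def test_mstop_zero_is_offset_only(self, rng):
        table, grid, theta = make_table(rng)
        offset = root_offset(theta)
        fit = boost_node(table, offset, grid, BoostConfig(m_stop=0))
        assert fit.gamma0 == 0.0
        assert np.all(fit.slopes == 0.0)
        assert np.all(fit.alpha == 0.0)
        np.testing.assert_array_equal(fit.fitted, offset[np.tile(np.arange(len(grid)), 40)])

    def test_decomposition_identity(self, rng):
        table, grid, theta = make_table(rng, n=60, p=3)
        offset = root_offset(theta)
        fit = boost_node(table, offset, grid, BoostConfig(nu=0.1, m_stop=150))
        X = table[[c for c in table.columns if c.startswith("x") and c != "x0"]].to_numpy()
        kidx = np.searchsorted(grid, table["time"].to_numpy())
        np.testing.assert_allclose(fit.linear_predictor(X, kidx), fit.fitted, atol=1e-10)

    def test_strong_signal_learner_dominates(self, rng):
        table, grid, theta = make_table(rng, n=100, signal=1.0)
        offset = root_offset(theta)
        fit = boost_node(table, offset, grid, BoostConfig(nu=0.1, m_stop=100))
        share = fit.selection.count("x1") / len(fit.selection)
        assert share >= 0.5
        assert fit.slopes[fit.columns.index("x1")] < 0  # higher x1 -> higher theta -> lower f

    def test_training_risk_nonincreasing(self, rng):
        table, grid, theta = make_table(rng, n=50, p=2, signal=0.5)
        offset = root_offset(theta)
        kidx = np.searchsorted(grid, table["time"].to_numpy())
        th = table["pseudo"].to_numpy()
        risks = []
        for m in range(0, 160, 20):
            fit = boost_node(table, offset, grid, BoostConfig(nu=0.01, m_stop=m))
            risks.append(loss(th, fit.fitted).sum())
        assert np.all(np.diff(risks) <= 1e-10)

    def test_zero_variance_covariate_excluded(self, rng):
        table, grid, theta = make_table(rng, n=30, p=2)
        table["x2"] = 1.0  # e.g. an ancestor's binary split variable
        fit = boost_node(table, root_offset(theta), grid, BoostConfig(nu=0.1, m_stop=60))
        assert fit.slopes[fit.columns.index("x2")] == 0.0
        assert "x2" not in fit.selection

    def test_monotone_baseline_invariant(self, rng):
        for _ in range(5):
            table, grid, theta = make_table(rng, n=40, p=2, signal=0.3)
            fit = boost_node(table, root_offset(theta), grid, BoostConfig(nu=0.05, m_stop=120))
            baseline = fit.offset + fit.gamma0 + fit.alpha
            assert np.all(np.diff(baseline) >= -1e-9)

    def test_shrinkage_of_noise_vs_signal(self, rng):
        sig, noi = [], []
        for _ in range(8):
            table, grid, theta = make_table(rng, n=80, p=3, signal=1.0)
            fit = boost_node(table, root_offset(theta), grid, BoostConfig(nu=0.05, m_stop=80))
            sig.append(abs(fit.slopes[fit.columns.index("x1")]))
            noi.append(np.mean(np.abs(fit.slopes[[fit.columns.index("x2"), fit.columns.index("x3")]])))
        assert np.mean(noi) < np.mean(sig)


class TestOffsets:
    def test_root_offset_is_link_transformed_km(self, rng):
        theta = rng.uniform(0, 1, (30, 4))
        np.testing.assert_allclose(
            root_offset(theta), cloglog_link(theta.mean(axis=0)), atol=1e-12
        )

    def test_child_equal_parent_mean(self, rng):
        K = 3
        fitted = rng.normal(size=60)
        kidx = np.tile(np.arange(K), 20)
        rows = np.arange(60)
        off = compute_offset(fitted, kidx, rows, K)
        np.testing.assert_allclose(off, fitted.reshape(20, 3).mean(axis=0))

    def test_monotone_parent_gives_monotone_offset(self, rng):
        K = 4
        base = np.sort(rng.normal(size=(15, K)), axis=1)
        fitted = base.reshape(-1)
        kidx = np.tile(np.arange(K), 15)
        rows = np.concatenate([np.arange(i * K, i * K + K) for i in range(0, 10)])
        off = compute_offset(fitted, kidx, rows, K)
        assert np.all(np.diff(off) >= 0)
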