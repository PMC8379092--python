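import numpy as np
import pytest

from diffperf.lasso import (
    LassoConfig,
    LassoError,
    cv_select_lambda,
    lambda_grid,
    lambda_max,
    lasso_fit,
)


def soft_threshold(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def orthonormal_design(n, p, rng):
    """Mutually orthogonal columns with zero mean and unit population
    SD (the ones-vector is included in the QR so the de-meaned columns
    stay orthogonal)."""
    A = np.c_[np.ones(n), rng.normal(size=(n, p))]
    q, _ = np.linalg.qr(A)
    X = q[:, 1:]
    return X / X.std(axis=0)


class TestLambdaMax:
    def test_orthogonal_response_gives_zero(self):
        rng = np.random.default_rng(0)
        X = orthonormal_design(40, 3, rng)
        y = np.zeros(40)
        assert lambda_max(X, y) == 0.0

    def test_definition_single_column(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std()
        y = 0.4 * x  # <x, y>/n = 0.4 by construction
        assert lambda_max(x[:, None], y) == pytest.approx(0.4)

    def test_fit_above_lambda_max_has_empty_support(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        Xs = (X - X.mean(0)) / X.std(0)
        lam = 1.01 * lambda_max(Xs, y - y.mean())
        fit = lasso_fit(Xs, y, lam)
        assert fit.selected_support == frozenset()
        assert fit.intercept == pytest.approx(y.mean())

    def test_zero_variance_column_rejected(self):
        X = np.c_[np.ones(10), np.arange(10.0)]
        with pytest.raises(LassoError):
            lambda_max(X, np.arange(10.0))


class TestLassoFit:
    def test_orthonormal_design_matches_soft_threshold(self):
        """On an orthonormal standardized design the lasso solution is
        coordinate-wise soft thresholding of <x_j, y>/n."""
        rng = np.random.default_rng(3)
        n, p = 60, 6
        X = orthonormal_design(n, p, rng)
        beta_true = np.array([2.0, -1.5, 0.8, 0.0, 0.3, -0.1])
        y = X @ beta_true + 0.1 * rng.normal(size=n)
        corr = X.T @ (y - y.mean()) / n
        for lam in (0.05, 0.2, 0.6):
            fit = lasso_fit(X, y, lam)
            expected = soft_threshold(corr, lam)
            np.testing.assert_allclose(fit.coefficients, expected, atol=1e-8)

    def test_zero_penalty_matches_ols(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=50)
        fit = lasso_fit(X, y, 0.0)
        A = np.c_[np.ones(50), X]
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        assert fit.intercept == pytest.approx(ols[0], abs=1e-6)
        np.testing.assert_allclose(fit.coefficients, ols[1:], atol=1e-6)

    def test_kkt_conditions_at_convergence(self):
        """|<x_j, r>/n| <= lam outside the support, == lam inside
        (standardized scale)."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 15))
        y = X[:, 0] - 2 * X[:, 3] + 0.5 * rng.normal(size=40)
        lam = 0.1
        fit = lasso_fit(X, y, lam)
        Xs = (X - X.mean(0)) / X.std(0)
        beta_s = fit.coefficients * X.std(0)
        r = (y - y.mean()) - Xs @ beta_s
        grad = np.abs(Xs.T @ r) / 40
        tol = 1e-6
        inside = np.array(sorted(fit.selected_support))
        outside = np.setdiff1d(np.arange(15), inside)
        assert np.all(grad[outside] <= lam + tol)
        np.testing.assert_allclose(grad[inside], lam, atol=tol)

    def test_support_monotone_on_orthonormal_design(self):
        rng = np.random.default_rng(6)
        X = orthonormal_design(50, 5, rng)
        y = X @ np.array([1.0, -0.7, 0.4, 0.2, 0.05]) + 0.05 * rng.normal(size=50)
        supports = [
            lasso_fit(X, y, lam).selected_support
            for lam in (0.02, 0.1, 0.3, 0.6, 1.0)
        ]
        for smaller_lam, larger_lam in zip(supports[:-1], supports[1:]):
            assert larger_lam <= smaller_lam

    def test_agreement_with_reference_implementation(self):
        """Supports identical and coefficients within 1e-4 of
        scikit-learn's coordinate-descent lasso at matched lambda."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(7)
        for trial in range(20):
            n, p = 40 + 2 * trial, 12
            X = rng.normal(size=(n, p))
            beta = np.zeros(p)
            beta[:3] = [1.2, -0.8, 0.5]
            y = X @ beta + 0.5 * rng.normal(size=n)
            Xs = (X - X.mean(0)) / X.std(0)
            lam = float(rng.uniform(0.02, 0.4))
            ours = lasso_fit(Xs, y, lam)
            ref = sklearn.Lasso(alpha=lam, tol=1e-12, max_iter=10 ** 6)
            ref.fit(Xs, y)
            ref_support = frozenset(np.flatnonzero(np.abs(ref.coef_) > 1e-10))
            assert ours.selected_support == ref_support
            np.testing.assert_allclose(ours.coefficients, ref.coef_,
                                       atol=1e-4)


class TestCvSelectLambda:
    def test_high_snr_signal_recovered(self):
        """With y exactly linear in 2 of 50 columns at high SNR the
        selected support contains both true columns."""
        hits = 0
        n_trials = 30
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 50))
            y = 2.0 * X[:, 4] - 1.5 * X[:, 17] + 0.05 * rng.normal(size=60)
            lam, _ = cv_select_lambda(X, y, seed=seed)
            fit = lasso_fit(X, y, lam)
            if {4, 17} <= set(fit.selected_support):
                hits += 1
        assert hits >= int(0.95 * n_trials)

    def test_degenerate_grid_returns_single_lambda(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 4))
        y = X[:, 0] + rng.normal(size=30)
        config = LassoConfig(n_lambda=1)
        lam, summary = cv_select_lambda(X, y, config, seed=0)
        assert len(summary["lambdas"]) == 1
        assert lam == summary["lambdas"][0]

    def test_pure_noise_keeps_support_small(self):
        sizes = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(40, 30))
            y = rng.normal(size=40)
            lam, _ = cv_select_lambda(X, y, seed=seed)
            sizes.append(len(lasso_fit(X, y, lam).selected_support))
        assert np.median(sizes) <= 3

    def test_constant_response_rejected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 4))
        with pytest.raises(LassoError):
            cv_select_lambda(X, np.ones(30), seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 10))
        y = X[:, 1] + rng.normal(size=40)
        a = cv_select_lambda(X, y, seed=5)
        b = cv_select_lambda(X, y, seed=5)
        assert a == b

    def test_grid_is_geometric(self):
        grid = lambda_grid(1.0, LassoConfig(n_lambda=5, lambda_min_ratio=1e-4))
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, ratios[0])
        assert grid[0] == 1.0 and grid[-1] == pytest.approx(1e-4)
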