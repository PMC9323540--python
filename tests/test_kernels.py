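"""SVR and GPR contracts: dual/QP and matrix-algebra oracles, selection."""

import itertools

import numpy as np
import pytest

from conftest import ols_oracle
from ilqspr.evaluation import cv_r2
from ilqspr.kernels import (
    DEFAULT_SVR_GRID,
    GprEstimator,
    HyperparamGrid,
    SvrEstimator,
    fit_gpr,
    fit_svr,
    greedy_substitution_select,
    predict_gpr,
    resolve_gamma,
    tune_svr,
)
from ilqspr.preprocess import assign_folds


def rbf_kernel(A, B, gamma):
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
    return np.exp(-gamma * d2)


def svr_dual_qp_oracle(X, y, C, epsilon, gamma):
    """Solve the ε-SVR dual as a generic constrained QP (SLSQP).

    Variables are the 2n split duals (a, a*) with 0 ≤ a_i, a*_i ≤ C and
    Σ(a_i − a*_i) = 0; the signed duals are β = a − a*.
    """
    from scipy.optimize import minimize

    n = len(y)
    K = rbf_kernel(X, X, gamma)

    def objective(z):
        a, astar = z[:n], z[n:]
        beta = a - astar
        return 0.5 * beta @ K @ beta + epsilon * z.sum() - y @ beta

    def gradient(z):
        a, astar = z[:n], z[n:]
        beta = a - astar
        g = K @ beta
        return np.concatenate([g + epsilon - y, -g + epsilon + y])

    result = minimize(
        objective,
        x0=np.full(2 * n, C / 4),
        jac=gradient,
        bounds=[(0.0, C)] * (2 * n),
        constraints=[{"type": "eq", "fun": lambda z: z[:n].sum() - z[n:].sum()}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert result.success, result.message
    return result.x[:n] - result.x[n:]


class TestSvr:
    def test_single_point_predicted_within_epsilon(self):
        model = fit_svr(np.array([[0.3]]), np.array([1.7]), C=10.0, epsilon=0.1)
        assert abs(model.predict([[0.3]])[0] - 1.7) <= 0.1 + 1e-9

    def test_line_toy_duals_match_qp_oracle(self, rng):
        X = np.linspace(-1, 1, 5).reshape(-1, 1)
        y = 0.5 + 1.5 * X.ravel()
        C, epsilon, gamma = 100.0, 0.01, 1.0
        model = fit_svr(X, y, C=C, epsilon=epsilon, gamma=gamma)
        assert np.all(np.abs(model.predict(X) - y) <= 2 * epsilon)
        beta_oracle = svr_dual_qp_oracle(X, y, C, epsilon, gamma)
        beta_mine = np.zeros(len(y))
        beta_mine[model.support_indices] = model.alphas
        assert np.allclose(beta_mine, beta_oracle, atol=1e-4)

    def test_dual_feasibility_bound(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        model = fit_svr(X, y, C=0.5, epsilon=0.01)
        assert np.all(np.abs(model.alphas) <= 0.5 + 1e-10)

    def test_gamma_token_semantics(self, rng):
        X = rng.normal(loc=2.0, scale=3.0, size=(15, 4))
        assert resolve_gamma("auto", X) == pytest.approx(1 / 4)
        assert resolve_gamma("scale", X) == pytest.approx(1 / (4 * X.var()))
        with pytest.raises(ValueError, match="token"):
            resolve_gamma("median", X)

    def test_nonpositive_hyperparameters_rejected(self, rng):
        X, y = rng.normal(size=(8, 2)), rng.normal(size=8)
        with pytest.raises(ValueError):
            fit_svr(X, y, C=-1.0)
        with pytest.raises(ValueError):
            fit_svr(X, y, epsilon=0.0)
        with pytest.raises(ValueError):
            fit_svr(X, y, gamma=-0.5)

    def test_wider_tube_never_adds_support_vectors(self, rng):
        X = rng.normal(size=(30, 1))
        y = np.sin(2 * X.ravel()) + 0.1 * rng.normal(size=30)
        counts = [
            fit_svr(X, y, C=10.0, epsilon=eps).n_support
            for eps in (0.01, 0.05, 0.1, 0.3, 0.6)
        ]
        assert np.all(np.diff(counts) <= 0)


class TestTuneSvr:
    def test_single_triple_grid_returned(self, rng):
        X, y = rng.normal(size=(20, 2)), rng.normal(size=20)
        folds = assign_folds(y, n_folds=5)
        grid = HyperparamGrid((2.0,), (0.05,), ("scale",))
        assert tune_svr(X, y, folds, grid) == (2.0, 0.05, "scale")

    def test_selects_gamma_that_scores_best(self, rng):
        # wiggly 1-D signal: a moderate kernel width generalizes, a very
        # narrow one memorizes; both candidates are scored explicitly
        X = np.sort(rng.uniform(-2, 2, size=15)).reshape(-1, 1)
        y = np.sin(2.0 * X.ravel()) + 0.05 * rng.normal(size=15)
        folds = assign_folds(y, n_folds=5)
        scores = {
            g: cv_r2(lambda: SvrEstimator(C=10.0, epsilon=0.01, gamma=g),
                     X, y, folds)
            for g in (0.5, 500.0)
        }
        assert scores[0.5] > scores[500.0]  # by construction
        grid = HyperparamGrid((10.0,), (0.01,), (0.5, 500.0))
        assert tune_svr(X, y, folds, grid)[2] == 0.5

    def test_default_grid_contents(self):
        assert DEFAULT_SVR_GRID.C_values == (
            0.001, 0.005, 0.1, 0.5, 1, 5, 10, 50, 100, 500, 1000,
        )
        assert DEFAULT_SVR_GRID.epsilon_values == (
            0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0,
        )
        assert DEFAULT_SVR_GRID.gamma_values == (
            0.001, 0.005, 0.01, 0.05, 0.1, "auto", "scale",
        )

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            HyperparamGrid((), (0.1,), (0.1,))
        with pytest.raises(ValueError):
            HyperparamGrid((1.0,), (-0.1,), (0.1,))
        with pytest.raises(ValueError):
            HyperparamGrid((1.0,), (0.1,), ("median",))


def composite_kernel_oracle(A, B, sigma_0, noise, ell, same):
    """The dot-product + RBF + white-noise kernel, written out by hand."""
    K = sigma_0**2 + A @ B.T
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
    K = K + np.exp(-d2 / (2 * ell**2))
    if same:
        K = K + noise * np.eye(A.shape[0])
    return K


class TestGpr:
    def test_interpolates_as_noise_vanishes(self, rng):
        X = rng.normal(size=(7, 2))
        y = rng.normal(size=7)
        model = fit_gpr(X, y, sigma_0=1.0, noise_level=1e-10,
                        length_scale=1.0, optimize=False)
        mean, _ = predict_gpr(model, X)
        assert np.allclose(mean, y, atol=1e-6)

    def test_three_point_mean_and_cov_match_direct_algebra(self, rng):
        X = np.array([[0.0, 0.1], [1.0, -0.4], [-0.6, 0.8]])
        y = np.array([0.5, -0.2, 0.9])
        sigma_0, noise, ell = 0.7, 0.05, 1.3
        model = fit_gpr(X, y, sigma_0=sigma_0, noise_level=noise,
                        length_scale=ell, optimize=False)
        Xs = np.array([[0.2, 0.0], [-1.0, 0.5]])
        mean, cov = predict_gpr(model, Xs)
        jitter = 1e-10  # matches the fit's base jitter
        Ktrain = composite_kernel_oracle(X, X, sigma_0, noise, ell, True)
        Ktrain = Ktrain + jitter * np.eye(3)
        Kcross = composite_kernel_oracle(Xs, X, sigma_0, noise, ell, False)
        Kself = composite_kernel_oracle(Xs, Xs, sigma_0, noise, ell, True)
        solve = np.linalg.solve(Ktrain, y)
        assert np.allclose(mean, Kcross @ solve, atol=1e-8)
        expected_cov = Kself - Kcross @ np.linalg.solve(Ktrain, Kcross.T)
        assert np.allclose(cov, expected_cov, atol=1e-8)

    def test_far_query_variance_reaches_prior_limit(self, rng):
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        sigma_0, noise, ell = 0.9, 0.01, 1.0
        model = fit_gpr(X, y, sigma_0=sigma_0, noise_level=noise,
                        length_scale=ell, optimize=False)
        far = np.array([[600.0, -800.0]])  # RBF cross-covariance ~ 0
        _, cov = predict_gpr(model, far)
        Ktrain = composite_kernel_oracle(X, X, sigma_0, noise, ell, True)
        Ktrain = Ktrain + 1e-10 * np.eye(6)
        kcross = sigma_0**2 + far @ X.T  # dot-product part only survives
        limit = (
            sigma_0**2 + float(far.ravel() @ far.ravel()) + 1.0 + noise
            - float((kcross @ np.linalg.solve(Ktrain, kcross.T)).item())
        )
        assert cov.shape == (1, 1) and cov[0, 0] >= 0
        assert cov[0, 0] == pytest.approx(limit, rel=1e-6)

    def test_descriptor_mismatch_lists_names(self, rng):
        model = fit_gpr(rng.normal(size=(5, 2)), rng.normal(size=5),
                        optimize=False, descriptor_names=["a", "b"])
        with pytest.raises(ValueError, match="'a', 'b'"):
            predict_gpr(model, rng.normal(size=(2, 3)))

    def test_optimization_never_lowers_marginal_likelihood(self, rng):
        X = rng.normal(size=(25, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + 0.2 * rng.normal(size=25)
        init = dict(sigma_0=1.0, noise_level=0.5, length_scale=2.0)
        fixed = fit_gpr(X, y, optimize=False, **init)
        tuned = fit_gpr(X, y, optimize=True, n_restarts=2, seed=3, **init)
        assert tuned.log_marginal_likelihood >= fixed.log_marginal_likelihood - 1e-8

    def test_dot_kernel_noise_limit_agrees_with_ols(self, rng):
        # RBF with an enormous length scale degenerates to a constant, so
        # the kernel is affine-linear; with vanishing noise the posterior
        # mean converges to the least-squares fit
        X = rng.normal(size=(20, 2))
        y = X @ np.array([0.8, -1.1]) + 0.3 * rng.normal(size=20)
        model = fit_gpr(X, y, sigma_0=5.0, noise_level=1e-8,
                        length_scale=1e8, optimize=False)
        Xq = rng.normal(size=(6, 2))
        mean, _ = predict_gpr(model, Xq)
        coef = ols_oracle(X, y)
        assert np.allclose(mean, coef[0] + Xq @ coef[1:], atol=1e-4)


class TestGreedySubstitution:
    @staticmethod
    def _ols_cv_score(X, y, folds, names):
        index = {d: j for j, d in enumerate(names)}

        def score(subset):
            from ilqspr.linear import _FixedSetOls

            cols = [index[d] for d in subset]
            return cv_r2(lambda: _FixedSetOls(list(subset)), X[:, cols], y, folds)

        return score

    def test_pool_equal_k_selects_everything(self, rng):
        X, y = rng.normal(size=(20, 3)), rng.normal(size=20)
        folds = assign_folds(y, n_folds=4)
        score = self._ols_cv_score(X, y, folds, ["a", "b", "c"])
        selected, _ = greedy_substitution_select(score, ["a", "b", "c"], 3)
        assert set(selected) == {"a", "b", "c"}

    def test_swap_recovers_planted_pair(self, rng):
        n = 50
        X = rng.normal(size=(n, 8))
        y = X[:, 2] + X[:, 5]  # exact in the planted pair
        X[:, 0] = y / np.std(y) + 0.4 * rng.normal(size=n)  # greedy decoy
        names = [f"d{j}" for j in range(8)]
        folds = assign_folds(y, n_folds=5)
        score = self._ols_cv_score(X, y, folds, names)
        assert score(("d0",)) > max(score(("d2",)), score(("d5",)))  # decoy first
        selected, final = greedy_substitution_select(score, names, 2)
        best_pair = max(
            itertools.combinations(names, 2), key=lambda pair: score(pair)
        )
        assert set(selected) == set(best_pair) == {"d2", "d5"}
        assert final == pytest.approx(score(tuple(selected)))

    def test_never_worse_than_pure_forward_selection(self, rng):
        for seed in (0, 1, 2):
            local = np.random.default_rng(seed)
            X = local.normal(size=(30, 6))
            y = X @ local.normal(size=6) + 0.5 * local.normal(size=30)
            names = [f"d{j}" for j in range(6)]
            folds = assign_folds(y, n_folds=5)
            score = self._ols_cv_score(X, y, folds, names)
            # pure forward selection, no substitution
            chosen: list = []
            for _ in range(3):
                rest = [d for d in names if d not in chosen]
                chosen.append(max(rest, key=lambda d: score(tuple(chosen + [d]))))
            _, with_subs = greedy_substitution_select(score, names, 3)
            assert with_subs >= score(tuple(chosen)) - 1e-12

    def test_pool_smaller_than_k_fails(self):
        with pytest.raises(ValueError, match="pool"):
            greedy_substitution_select(lambda s: 0.0, ["a"], 2)
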