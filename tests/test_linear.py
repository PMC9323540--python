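"""OLS, orthogonal matching pursuit, the expulsion search and the size rule."""

import itertools

import numpy as np
import pytest

from conftest import ols_oracle
from ilqspr.evaluation import r2
from ilqspr.linear import (
    LinearModel,
    choose_model_size,
    expulsion_search,
    fit_ols,
    omp_select,
)
from ilqspr.preprocess import assign_folds, standardize
from ilqspr.io import DescriptorMatrix


def _standardized(rng, n, p):
    m = DescriptorMatrix(
        row_ids=[f"r{i}" for i in range(n)],
        descriptor_names=[f"d{j}" for j in range(p)],
        values=rng.normal(size=(n, p)),
    )
    return standardize(m)


def exhaustive_best_subset(X, y, k):
    """RSS-minimizing size-k subset by enumeration (independent oracle)."""
    best, best_rss = None, np.inf
    for combo in itertools.combinations(range(X.shape[1]), k):
        coef = ols_oracle(X[:, combo], y)
        resid = y - np.hstack([np.ones((len(y), 1)), X[:, combo]]) @ coef
        rss = float(resid @ resid)
        if rss < best_rss - 1e-12:
            best, best_rss = set(combo), rss
    return best


class TestFitOls:
    def test_noise_free_linear_data_fits_exactly(self, rng):
        X = rng.normal(size=(15, 3))
        y = 2.0 + X @ np.array([1.0, -2.0, 0.5])
        model = fit_ols(X, y)
        assert np.allclose(model.predict(X), y)
        assert r2(y, model.predict(X)) == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        model = fit_ols(X, y)
        expected = ols_oracle(X, y)
        assert model.beta0 == pytest.approx(expected[0], abs=1e-8)
        assert np.allclose(model.betas, expected[1:], atol=1e-8)

    def test_intercept_equals_mean_y_on_standardized_x(self, rng):
        std = _standardized(rng, 20, 4)
        y = rng.normal(size=20)
        model = fit_ols(std.values, y, descriptor_names=std.descriptor_names)
        assert model.beta0 == pytest.approx(float(y.mean()), abs=1e-9)

    def test_rank_deficient_design_names_columns(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        with pytest.raises(np.linalg.LinAlgError, match="dependent"):
            fit_ols(X, rng.normal(size=10), descriptor_names=["a", "b", "absum"])

    def test_needs_more_rows_than_columns(self, rng):
        with pytest.raises(ValueError, match="n > k\\+1"):
            fit_ols(rng.normal(size=(4, 3)), rng.normal(size=4))

    def test_standardized_betas_equal_raw_betas_times_sd(self, rng):
        raw = DescriptorMatrix(
            row_ids=[f"r{i}" for i in range(25)],
            descriptor_names=["a", "b", "c"],
            values=rng.normal(loc=5, scale=3, size=(25, 3)),
        )
        y = rng.normal(size=25)
        std = standardize(raw)
        m_std = fit_ols(std.values, y)
        m_raw = fit_ols(raw.values, y)
        assert np.allclose(m_std.betas, m_raw.betas * std.column_sds, atol=1e-8)

    def test_json_roundtrip(self, rng):
        model = fit_ols(rng.normal(size=(10, 2)), rng.normal(size=10),
                        descriptor_names=["VE2_A", "Xpc-4d"])
        back = LinearModel.from_json(model.to_json())
        assert back.descriptor_names == model.descriptor_names
        assert np.allclose(back.betas, model.betas)
        assert back.beta0 == model.beta0


class TestOmp:
    def test_exact_single_column_found_first(self, rng):
        std = _standardized(rng, 20, 6)
        y = std.values[:, 3].copy()
        model = omp_select(std.values, y, 1, descriptor_names=std.descriptor_names)
        assert model.descriptor_names == ["d3"]
        assert np.allclose(model.predict(std.values[:, [3]]), y, atol=1e-10)

    def test_planted_pair_matches_exhaustive_search(self, rng):
        std = _standardized(rng, 20, 8)
        y = std.values[:, 2] * 1.5 - std.values[:, 6] * 1.0  # noise-free
        model = omp_select(std.values, y, 2, descriptor_names=std.descriptor_names)
        oracle = exhaustive_best_subset(std.values, y, 2)
        assert {std.descriptor_names.index(d) for d in model.descriptor_names} == oracle

    def test_k_zero_gives_intercept_only(self, rng):
        y = rng.normal(size=10)
        model = omp_select(rng.normal(size=(10, 3)), y, 0)
        assert model.descriptor_names == []
        assert model.beta0 == pytest.approx(float(y.mean()))

    def test_early_stop_on_zero_residual(self, rng):
        std = _standardized(rng, 15, 5)
        y = std.values[:, 1].copy()
        model = omp_select(std.values, y, 4, descriptor_names=std.descriptor_names)
        assert model.descriptor_names == ["d1"]  # smaller model returned

    def test_k_equal_p_reproduces_full_ols(self, rng):
        std = _standardized(rng, 30, 5)
        y = rng.normal(size=30)
        omp = omp_select(std.values, y, 5, descriptor_names=std.descriptor_names)
        full = fit_ols(std.values, y, descriptor_names=std.descriptor_names)
        order = [omp.descriptor_names.index(d) for d in std.descriptor_names]
        assert np.allclose(omp.betas[order], full.betas, atol=1e-8)

    def test_training_r2_nondecreasing_in_k(self, rng):
        std = _standardized(rng, 40, 8)
        y = std.values[:, 0] - 0.5 * std.values[:, 4] + rng.normal(size=40)
        scores = []
        for k in range(1, 7):
            model = omp_select(std.values, y, k, descriptor_names=std.descriptor_names)
            cols = [std.descriptor_names.index(d) for d in model.descriptor_names]
            scores.append(r2(y, model.predict(std.values[:, cols])))
        assert np.all(np.diff(scores) >= -1e-12)

    def test_agrees_with_reference_omp_implementation(self, rng):
        from sklearn.linear_model import OrthogonalMatchingPursuit

        std = _standardized(rng, 50, 12)
        y = (std.values[:, 1] * 1.2 - std.values[:, 7] * 0.8
             + 0.3 * rng.normal(size=50))
        mine = omp_select(std.values, y, 3, descriptor_names=std.descriptor_names)
        ref = OrthogonalMatchingPursuit(n_nonzero_coefs=3).fit(std.values, y)
        ref_support = {f"d{j}" for j in np.flatnonzero(ref.coef_)}
        assert set(mine.descriptor_names) == ref_support


class TestExpulsionSearch:
    def test_low_correlation_pool_runs_single_round(self, rng):
        n = 200  # large n keeps sample correlations of independent noise small
        std = _standardized(rng, n, 6)
        y = rng.normal(size=n)  # independent of X: all |corr| << 0.4
        folds = assign_folds(y, n_folds=10)
        _, trace = expulsion_search(
            std.values, y, folds, 2, descriptor_names=std.descriptor_names
        )
        assert len(trace.rounds) == 1
        assert trace.rounds[0].expelled is None
        assert "< 0.4" in trace.stop_reason

    def test_decoy_masking_exact_pair_is_beaten(self, rng):
        n = 40
        std = _standardized(rng, n, 6)
        x1, x2 = std.values[:, 0], std.values[:, 1]
        y = x1 + x2  # exact in the pair
        # single proxy strongly correlated with y but not exact
        proxy = (y / np.std(y) + 0.45 * rng.normal(size=n))
        values = np.column_stack([std.values, proxy])
        names = std.descriptor_names + ["proxy"]
        folds = assign_folds(y, n_folds=10)
        model, trace = expulsion_search(values, y, folds, 2, descriptor_names=names)
        assert trace.best_round > 0  # a post-expulsion candidate won
        oracle = exhaustive_best_subset(values, y, 2)
        assert {names.index(d) for d in model.descriptor_names} == oracle
        assert trace.rounds[trace.best_round].cv_r2 == pytest.approx(1.0, abs=1e-9)

    def test_pool_exhaustion_returns_best_so_far(self, rng):
        n = 30
        std = _standardized(rng, n, 2)
        y = std.values @ np.array([1.0, 0.9])  # both columns correlate strongly
        folds = assign_folds(y, n_folds=5)
        model, trace = expulsion_search(
            std.values, y, folds, 2, descriptor_names=std.descriptor_names
        )
        assert trace.stop_reason == "pool exhausted"
        assert len(model.descriptor_names) >= 1

    def test_expelled_descriptors_still_usable_in_candidates(self, rng):
        # candidate from round 0 may contain the descriptor expelled later
        n = 40
        std = _standardized(rng, n, 5)
        y = std.values[:, 0] + 0.1 * rng.normal(size=n)
        folds = assign_folds(y, n_folds=10)
        model, trace = expulsion_search(
            std.values, y, folds, 1, descriptor_names=std.descriptor_names
        )
        expelled = {r.expelled for r in trace.rounds} - {None}
        assert "d0" in expelled  # top-correlated descriptor was expelled
        assert model.descriptor_names == ["d0"]  # yet the best model keeps it


class TestChooseModelSize:
    def _builder(self, errs):
        def build(k):
            return f"model{k}", errs[k - 1]

        return build

    def test_twenty_percent_boundary_accepts(self):
        model, k = choose_model_size(self._builder([0.10, 0.08, 0.075]), 3)
        assert k == 2  # (0.10-0.08)/0.10 = 0.20 accepted; next step 6% rejected

    def test_error_increase_keeps_k1(self):
        model, k = choose_model_size(self._builder([0.10, 0.12]), 2)
        assert (model, k) == ("model1", 1)

    def test_partial_growth(self):
        model, k = choose_model_size(self._builder([0.30, 0.21, 0.18]), 3)
        assert k == 2  # 30% accepted, then 14% rejected

    def test_zero_error_stops_immediately(self):
        model, k = choose_model_size(self._builder([0.0, 0.0]), 2)
        assert k == 1

    def test_k_max_caps_growth(self):
        model, k = choose_model_size(self._builder([0.4, 0.2, 0.1, 0.05]), 2)
        assert k == 2
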