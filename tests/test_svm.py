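"""SVR engine: kernels, dual-form predictions vs a QP oracle, CV, grid search,
feature weights, serialization."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from castesvm.preprocess import Scaler
from castesvm.svm import (CVResult, KernelSpec, SVRModel, cross_validation_error,
                          default_refined_grid, feature_weights, fit_svr,
                          grid_search, kernel_matrix, kernel_value, predict,
                          study_scaled_gamma)


def qp_svr_oracle(X, y, spec, C, eps):
    """Independent solve of the epsilon-SVR dual by SLSQP.

    Variables are the split multipliers (alpha, alpha*); returns the signed
    dual vector beta = alpha - alpha* and the intercept from free support
    vectors' KKT conditions.
    """
    K = kernel_matrix(spec, X, X)
    n = len(y)

    def obj(z):
        b = z[:n] - z[n:]
        return 0.5 * b @ K @ b + eps * z.sum() - y @ b

    def grad(z):
        Kb = K @ (z[:n] - z[n:])
        return np.concatenate([Kb + eps - y, -Kb + eps + y])

    cons = {"type": "eq", "fun": lambda z: z[:n].sum() - z[n:].sum(),
            "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])}
    res = minimize(obj, np.zeros(2 * n), jac=grad, method="SLSQP",
                   bounds=[(0, C)] * (2 * n), constraints=[cons],
                   options={"maxiter": 2000, "ftol": 1e-14})
    assert res.success
    beta = res.x[:n] - res.x[n:]
    free = (np.abs(beta) > 1e-7) & (np.abs(beta) < C - 1e-7)
    assert free.any()
    Kb = K @ beta
    b = np.mean(y[free] - Kb[free] - eps * np.sign(beta[free]))
    return beta, b


class TestKernels:
    def test_radial_identical_points(self):
        spec = KernelSpec("radial", gamma=3.7)
        assert kernel_value(spec, [1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_radial_closed_form(self):
        spec = KernelSpec("radial", gamma=0.5)
        assert kernel_value(spec, (1, 0), (0, 0)) == pytest.approx(math.exp(-0.5))

    def test_linear_dot_product(self):
        assert kernel_value(KernelSpec("linear"), (1, 2), (3, 4)) == pytest.approx(11)

    def test_sigmoid_and_polynomial(self):
        assert kernel_value(KernelSpec("sigmoid", gamma=0.1, coef0=0.2),
                            (1, 2), (3, 4)) == pytest.approx(math.tanh(1.3))
        assert kernel_value(KernelSpec("polynomial", gamma=1.0, coef0=1.0, degree=2),
                            (1, 2), (3, 4)) == pytest.approx(144.0)

    @pytest.mark.parametrize("spec", [
        KernelSpec("radial", gamma=0.3), KernelSpec("linear"),
        KernelSpec("sigmoid", gamma=0.2, coef0=0.1),
        KernelSpec("polynomial", gamma=0.5, coef0=1.0, degree=3),
    ])
    def test_symmetry_and_radial_range(self, spec):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        K = kernel_matrix(spec, X, X)
        assert np.allclose(K, K.T, atol=1e-12)
        if spec.kind == "radial":
            assert np.all(K > 0) and np.all(K <= 1.0 + 1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            kernel_value(KernelSpec("linear"), (1, 2), (1, 2, 3))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("radial", gamma=-1.0)
        with pytest.raises(ValueError):
            KernelSpec("gaussian", gamma=1.0)


class TestFitSVR:
    def test_constant_response_degenerate(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        model = fit_svr(X, np.full(10, 0.7), KernelSpec("radial", gamma=1.0),
                        C=10.0, epsilon=0.1)
        assert np.allclose(predict(model, X), 0.7, atol=1e-6)
        assert np.allclose(model.dual_coef, 0.0, atol=1e-9) or \
            model.dual_coef.size == 0

    def test_two_point_symmetry(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0.0, 1.0])
        model = fit_svr(X, y, KernelSpec("radial", gamma=1.0), C=10.0,
                        epsilon=0.01)
        assert predict(model, [[0.0]])[0] == pytest.approx(0.5, abs=1e-6)

    def test_dual_coef_bounded_by_C(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 2))
        y = np.sin(X[:, 0])
        model = fit_svr(X, y, KernelSpec("radial", gamma=1.0), C=0.5,
                        epsilon=0.01)
        assert np.all(np.abs(model.dual_coef) <= 0.5 + 1e-9)

    def test_nonfinite_features_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError):
            fit_svr(X, np.array([0.0, 1.0]), KernelSpec("linear"), 1.0, 0.1)

    @pytest.mark.parametrize("trial", range(5))
    def test_predictions_match_qp_oracle(self, trial):
        """Fitted predictions agree with an independent quadratic-programming
        solve of the SVR dual on 20-sample toys."""
        rng = np.random.default_rng(100 + trial)
        X = rng.normal(size=(20, 1))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=20)
        spec = KernelSpec("radial", gamma=0.5)
        C, eps = 10.0, 0.05
        model = fit_svr(X, y, spec, C, eps, tol=1e-10)
        beta, b = qp_svr_oracle(X, y, spec, C, eps)
        grid = np.linspace(-2.5, 2.5, 41)[:, None]
        ours = predict(model, grid)
        oracle = kernel_matrix(spec, grid, X) @ beta + b
        assert np.max(np.abs(ours - oracle)) < 1e-5


class TestPredict:
    def _hand_model(self):
        return SVRModel(
            kernel=KernelSpec("radial", gamma=1.0), C=1.0, epsilon=0.1,
            support_vectors=np.array([[1.0, 0.0], [0.0, 1.0]]),
            dual_coef=np.array([0.5, -0.25]), intercept=0.1,
            gene_ids=["gx", "gy"])

    def test_hand_built_dual_sum(self):
        model = self._hand_model()
        x = np.array([0.5, 0.5])
        expected = (0.5 * math.exp(-((0.5) ** 2 + (0.5) ** 2))
                    - 0.25 * math.exp(-((0.5) ** 2 + (0.5) ** 2)) + 0.1)
        assert predict(model, [x])[0] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_query_rows_identical(self):
        model = self._hand_model()
        out = predict(model, [[0.2, 0.7], [0.2, 0.7]])
        assert out[0] == out[1]

    def test_zero_alpha_returns_intercept(self):
        model = self._hand_model()
        model.dual_coef = np.zeros(2)
        assert np.allclose(predict(model, [[5.0, -3.0]]), 0.1)

    def test_gene_order_mismatch_raises(self):
        model = self._hand_model()
        with pytest.raises(ValueError):
            predict(model, [[0.0, 0.0]], gene_ids=["gy", "gx"])


class TestFeatureWeights:
    def test_hand_matrix_product(self):
        model = SVRModel(
            kernel=KernelSpec("linear"), C=1.0, epsilon=0.1,
            support_vectors=np.array([[1.0, 2.0], [0.0, 1.0]]),
            dual_coef=np.array([1.0, -1.0]), intercept=0.0,
            gene_ids=["a", "b"])
        assert feature_weights(model) == {"a": 1.0, "b": 1.0}

    def test_all_zero_alpha_gives_zero_weights(self):
        model = SVRModel(
            kernel=KernelSpec("linear"), C=1.0, epsilon=0.1,
            support_vectors=np.zeros((0, 2)), dual_coef=np.zeros(0),
            intercept=0.3, gene_ids=["a", "b"])
        assert feature_weights(model) == {"a": 0.0, "b": 0.0}

    def test_brute_force_sum_on_fitted_model(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 5))
        y = X[:, 0] - 0.5 * X[:, 3] + 0.05 * rng.normal(size=12)
        model = fit_svr(X, y, KernelSpec("radial", gamma=0.2), 5.0, 0.01)
        w = feature_weights(model)
        for j, g in enumerate(model.gene_ids):
            brute = sum(a * s[j] for a, s in
                        zip(model.dual_coef, model.support_vectors))
            assert w[g] == pytest.approx(brute, abs=1e-12)

    def test_linear_kernel_matches_finite_difference_gradient(self):
        """For a linear kernel, alpha^T S is the gradient of the decision
        function, recoverable by finite differences."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.05 * rng.normal(size=10)
        model = fit_svr(X, y, KernelSpec("linear"), 10.0, 0.01, tol=1e-10)
        w = feature_weights(model)
        x0 = np.zeros(3)
        h = 1e-5
        for j, g in enumerate(model.gene_ids):
            e = np.zeros(3)
            e[j] = h
            fd = (predict(model, [x0 + e])[0] - predict(model, [x0 - e])[0]) / (2 * h)
            assert w[g] == pytest.approx(fd, abs=1e-4)


class TestCrossValidation:
    def test_constant_response_zero_error(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        cv = cross_validation_error(X, np.full(12, 0.4),
                                    KernelSpec("radial", gamma=0.5), 10.0, 0.1,
                                    repeats=3, seed=0)
        assert cv.mse == pytest.approx(0.0, abs=1e-10)

    def test_chance_level_for_permuted_labels(self):
        """Labels independent of features: MSE near the variance of a
        balanced 0/1 response (0.25)."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 10))
        y = np.repeat([0.0, 1.0], 20)
        y = rng.permutation(y)
        cv = cross_validation_error(X, y, KernelSpec("radial", gamma=0.1),
                                    10.0, 0.1, repeats=10, seed=11)
        assert 0.15 <= cv.mse <= 0.40

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            cross_validation_error(np.zeros((3, 1)), np.zeros(3),
                                   KernelSpec("linear"), 1.0, 0.1, k=4)

    def test_mean_equals_mean_of_repeat_errors(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        cv = cross_validation_error(X, y, KernelSpec("radial", gamma=0.3),
                                    2.0, 0.1, repeats=4, seed=3)
        assert cv.mse == pytest.approx(np.mean(cv.repeat_errors))
        assert cv.rmse == pytest.approx(math.sqrt(cv.mse))

    def test_invariant_to_sample_order_with_ids(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(14, 3))
        y = rng.normal(size=14)
        ids = [f"s{i:02d}" for i in range(14)]
        cv1 = cross_validation_error(X, y, KernelSpec("radial", gamma=0.5),
                                     5.0, 0.1, repeats=3, seed=9, sample_ids=ids)
        perm = rng.permutation(14)
        cv2 = cross_validation_error(X[perm], y[perm],
                                     KernelSpec("radial", gamma=0.5),
                                     5.0, 0.1, repeats=3, seed=9,
                                     sample_ids=[ids[i] for i in perm])
        assert cv1.mse == pytest.approx(cv2.mse, abs=1e-12)


class TestGridSearch:
    def test_single_point_grid(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        grid = [(KernelSpec("radial", gamma=0.5), 1.0)]
        res = grid_search(X, y, grid, repeats=2, seed=0)
        assert res.selected == grid[0]

    def test_selection_equals_exhaustive_argmin(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=16)
        grid = [(KernelSpec("radial", gamma=g), c)
                for g in (1e-3, 0.1, 10.0) for c in (0.01, 10.0)]
        res = grid_search(X, y, grid, repeats=3, seed=4)
        manual = [cross_validation_error(X, y, s, c, 0.1, repeats=3, seed=4).mse
                  for s, c in grid]
        assert res.selected_index == int(np.argmin(manual))

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((5, 1)), np.zeros(5), [])

    def test_default_grid_is_within_refined_bounds(self):
        grid = default_refined_grid()
        assert len(grid) == 25
        for spec, C in grid:
            assert spec.kind == "radial"
            assert 2 ** 4 < C < 2 ** 6
            assert 1e-7 < spec.gamma < 1e-5

    def test_study_operating_point_at_study_scale(self):
        # the documented default: gamma = 1e-6 at the study's 10,734 genes
        assert study_scaled_gamma(10734) == pytest.approx(1e-6)


class TestSerialization:
    def test_bit_exact_round_trip(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = fit_svr(X, y, KernelSpec("radial", gamma=0.123456789), 3.0, 0.05,
                        gene_ids=list("abcd"))
        model.scaler = Scaler(
            mean=__import__("pandas").Series({"a": 0.1, "b": -0.2, "c": 0.0,
                                              "d": 1e-17}),
            sd=__import__("pandas").Series({"a": 1.0, "b": 2.0, "c": 0.5,
                                            "d": 3.0}),
            dropped=["zz"])
        model.normalization = {"pseudocount": 1.0, "transform": "log2-cpm"}
        text = model.to_json()
        back = SVRModel.from_json(text)
        assert back.to_json() == text
        assert np.array_equal(back.support_vectors, model.support_vectors)
        assert np.array_equal(back.dual_coef, model.dual_coef)
        assert back.intercept == model.intercept
        assert back.kernel == model.kernel
        rngq = np.random.default_rng(9)
        q = rngq.normal(size=(5, 4))
        assert np.array_equal(predict(back, q), predict(model, q))
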