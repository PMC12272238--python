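"""KRR and LRR: closed-form oracles, tuning behavior, masking contracts."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

import metamatch as mm
from metamatch.exceptions import ProtocolError, ValidationError
from metamatch.features import correlation_kernel
from metamatch.learners import tune_krr_kernel


@pytest.fixture
def small_problem():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(6, 15))
    y = rng.normal(size=6)
    return x, y


class TestKRRFit:
    def test_matches_dense_solver_oracle(self, small_problem):
        """Predictions equal a generic linear solve of (K + lam I) a = y_c."""
        x, y = small_problem
        lam = 0.7
        model = mm.fit_krr(x, y, lam)
        k = correlation_kernel(x)
        alpha = np.linalg.solve(k + lam * np.eye(6), y - y.mean())
        x_new = np.random.default_rng(12).normal(size=(3, 15))
        expected = correlation_kernel(x_new, x) @ alpha + y.mean()
        np.testing.assert_allclose(model.predict(x_new), expected, atol=1e-10)

    def test_dual_residual_satisfies_system(self, small_problem):
        x, y = small_problem
        lam = 0.3
        model = mm.fit_krr(x, y, lam)
        k = correlation_kernel(x)
        resid = (k + lam * np.eye(6)) @ model.dual_coefs[0] - (y - y.mean())
        assert np.linalg.norm(resid) / np.linalg.norm(y - y.mean()) < 1e-6

    def test_identity_kernel_unit_lambda_halves_targets(self):
        """(I + I) alpha = y_c gives alpha = y_c / 2 exactly."""
        y = np.array([2.0, -2.0, 4.0, -4.0])
        x = np.random.default_rng(13).normal(size=(4, 10))
        model = mm.fit_krr(x, y, lam=1.0, kernel=np.eye(4))
        np.testing.assert_allclose(model.dual_coefs[0], (y - y.mean()) / 2, atol=1e-12)

    def test_large_lambda_shrinks_to_mean(self, small_problem):
        x, y = small_problem
        model = mm.fit_krr(x, y, lam=1e9)
        assert np.linalg.norm(model.dual_coefs[0]) < 1e-6
        x_new = np.random.default_rng(14).normal(size=(4, 15))
        np.testing.assert_allclose(model.predict(x_new), y.mean(), atol=1e-6)

    def test_interpolates_training_points_at_tiny_lambda(self, small_problem):
        x, y = small_problem
        model = mm.fit_krr(x, y, lam=1e-10)
        np.testing.assert_allclose(model.predict(x), y, atol=1e-5)

    def test_constant_targets_predict_constant(self, small_problem):
        x, _ = small_problem
        model = mm.fit_krr(x, np.full(6, 5.0), lam=0.1)
        np.testing.assert_allclose(
            model.predict(np.random.default_rng(15).normal(size=(3, 15))),
            5.0, atol=1e-10,
        )

    def test_predictions_invariant_to_affine_feature_rescaling(self, small_problem):
        x, y = small_problem
        model_a = mm.fit_krr(x, y, lam=0.5)
        scales = np.random.default_rng(16).uniform(0.5, 2.0, size=(6, 1))
        model_b = mm.fit_krr(x * scales + 1.7, y, lam=0.5)
        x_new = np.random.default_rng(17).normal(size=(3, 15))
        np.testing.assert_allclose(
            model_a.predict(x_new), model_b.predict(x_new), atol=1e-10
        )

    def test_feature_length_mismatch_rejected(self, small_problem):
        x, y = small_problem
        model = mm.fit_krr(x, y, 0.5)
        with pytest.raises(ValidationError, match="length"):
            model.predict(np.zeros((2, 14)))


class TestKRRTuning:
    def test_single_lambda_grid_returns_it(self, small_problem):
        x, y = small_problem
        lam, _ = mm.tune_krr(x, y, lambda_grid=np.array([0.37]), n_folds=3)
        assert lam == 0.37

    def test_noiseless_kernel_target_prefers_smallest_lambda(self):
        """If y is exactly linear in a kernel column, no shrinkage helps."""
        rng = np.random.default_rng(18)
        x = rng.normal(size=(40, 100))  # E > n keeps the kernel full rank
        y = correlation_kernel(x)[:, 0] * 3.0
        grid = np.array([1e-4, 1e-1, 1e2])
        lam, _ = mm.tune_krr(x, y, lambda_grid=grid, seed=1)
        assert lam == 1e-4

    def test_tie_breaks_to_largest_lambda(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        # duplicated lambda value: scores tie exactly, largest (equal) chosen
        k = correlation_kernel(x)
        lam, scores = tune_krr_kernel(k, y, np.array([0.5, 0.5]), seed=2)
        assert scores[0] == scores[1] and lam == 0.5

    def test_cv_deterministic_in_seed(self, small_problem):
        x, y = small_problem
        a = mm.tune_krr(x, y, seed=42)
        b = mm.tune_krr(x, y, seed=42)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])

    def test_fewer_participants_than_folds_rejected(self):
        x = np.random.default_rng(20).normal(size=(3, 5))
        with pytest.raises(ProtocolError, match="folds"):
            mm.tune_krr(x, np.arange(3.0), n_folds=5)


class TestLRR:
    def test_univariate_noiseless_slope(self):
        x = np.linspace(0, 1, 50)[:, None]
        model = mm.fit_lrr(x, 2.0 * x[:, 0], lambda_grid=np.array([1e-8]))
        assert model.weights[0] == pytest.approx(2.0, abs=1e-4)

    def test_matches_normal_equations_oracle(self):
        """Weights agree with an independent solve of (Xc'Xc + lam I) w = Xc'y."""
        rng = np.random.default_rng(21)
        x = rng.normal(size=(50, 10))
        y = rng.normal(size=50)
        lam = 2.5
        model = mm.fit_lrr(x, y, lambda_grid=np.array([lam]))
        xc = x - x.mean(axis=0)
        w = np.linalg.solve(xc.T @ xc + lam * np.eye(10), xc.T @ (y - y.mean()))
        np.testing.assert_allclose(model.weights, w, atol=1e-8)
        assert model.intercept == pytest.approx(
            y.mean() - x.mean(axis=0) @ w, abs=1e-8
        )

    def test_matches_sklearn_ridge(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=(60, 12))
        y = x @ rng.normal(size=12) + rng.normal(size=60)
        lam = 1.3
        model = mm.fit_lrr(x, y, lambda_grid=np.array([lam]))
        sk = Ridge(alpha=lam).fit(x, y)
        np.testing.assert_allclose(model.weights, sk.coef_, atol=1e-8)
        x_new = rng.normal(size=(5, 12))
        np.testing.assert_allclose(
            model.predict(x_new), sk.predict(x_new), atol=1e-8
        )

    def test_infinite_lambda_limit(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        model = mm.fit_lrr(x, y, lambda_grid=np.array([1e12]))
        assert np.linalg.norm(model.weights) < 1e-6
        assert model.intercept == pytest.approx(y.mean(), abs=1e-5)

    def test_all_missing_phenotype_rejected(self):
        x = np.random.default_rng(24).normal(size=(10, 3))
        with pytest.raises(ValidationError, match="observed"):
            mm.fit_lrr(x, np.zeros(10), mask=np.zeros(10, dtype=bool))


class TestMaskedFitting:
    def test_masked_cells_never_influence_models(self):
        """Arbitrary garbage in masked cells leaves KRR and LRR untouched."""
        rng = np.random.default_rng(25)
        x = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        mask = rng.random(30) > 0.3
        y_poisoned = y.copy()
        y_poisoned[~mask] = 1e6

        krr_a = mm.fit_krr(x, y, 0.5, mask=mask)
        krr_b = mm.fit_krr(x, y_poisoned, 0.5, mask=mask)
        np.testing.assert_array_equal(krr_a.dual_coefs[0], krr_b.dual_coefs[0])

        lrr_a = mm.fit_lrr(x, y, seed=3, mask=mask)
        lrr_b = mm.fit_lrr(x, y_poisoned, seed=3, mask=mask)
        np.testing.assert_array_equal(lrr_a.weights, lrr_b.weights)
        assert lrr_a.lam == lrr_b.lam


def test_krr_equals_primal_ridge_on_normalized_features():
    """On zero-mean unit-norm rows the correlation kernel is the linear
    kernel, so dual KRR must match primal ridge with the same lambda."""
    rng = np.random.default_rng(26)
    x = mm.normalize_features(rng.normal(size=(12, 20)))
    y = rng.normal(size=12)
    lam = 0.8
    krr = mm.fit_krr(x, y, lam)
    xc = x  # rows already centered per participant; no column centering used
    w = xc.T @ np.linalg.solve(xc @ xc.T + lam * np.eye(12), y - y.mean())
    x_new = mm.normalize_features(rng.normal(size=(4, 20)))
    np.testing.assert_allclose(
        krr.predict(x_new), x_new @ w + y.mean(), atol=1e-6
    )
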