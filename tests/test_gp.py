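"""GP regression core: oracle equivalence, hyperparameter behavior, calibration."""

import numpy as np
import pytest
from scipy import stats

from normap.gp import (
    SE_ARD,
    DegenerateResponseError,
    GPModel,
    Kernel,
    ValidationError,
    fit_gp,
    kernel_matrix,
    log_marginal_likelihood,
    predict_gp,
)


def dense_gp_oracle(kern, noise, X, y, Xs):
    """Textbook closed-form GP posterior via explicit inverse (independent
    of the Cholesky implementation path)."""
    K = kernel_matrix(kern, X, X) + noise * np.eye(len(X))
    Kinv = np.linalg.inv(K)
    Ks = kernel_matrix(kern, X, Xs)
    mean = Ks.T @ Kinv @ y
    kss = np.array([kernel_matrix(kern, x[None, :], x[None, :])[0, 0] for x in Xs])
    var = kss - np.einsum("ij,ik,kj->j", Ks, Kinv, Ks)
    sign, logdet = np.linalg.slogdet(K)
    lml = -0.5 * y @ Kinv @ y - 0.5 * logdet - 0.5 * len(y) * np.log(2 * np.pi)
    return mean, var, lml


@pytest.fixture
def kern2d():
    return Kernel(SE_ARD, np.array([0.5, 2.0]), 1.7)


class TestKernelMatrix:
    def test_self_covariance_is_signal_variance(self, kern2d):
        x = np.array([[0.3, -1.2]])
        assert kernel_matrix(kern2d, x, x)[0, 0] == pytest.approx(1.7)

    def test_one_length_scale_separation(self):
        kern = Kernel(SE_ARD, np.array([0.5]), 2.0)
        K = kernel_matrix(kern, np.array([[0.0]]), np.array([[0.5]]))
        assert K[0, 0] == pytest.approx(2.0 * np.exp(-0.5))

    def test_matches_entrywise_scalar_loop(self, kern2d):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 2))
        K = kernel_matrix(kern2d, A, A)
        for a in range(3):
            for b in range(3):
                d = (A[a] - A[b]) / kern2d.length_scales
                expect = 1.7 * np.exp(-0.5 * np.sum(d**2))
                assert K[a, b] == pytest.approx(expect, rel=1e-12)
        assert np.allclose(K, K.T)

    def test_linear_se_sum(self):
        kern = Kernel("linear_se_ard", np.array([1.0]), 1.0, linear_variance=0.5)
        A, B = np.array([[2.0]]), np.array([[3.0]])
        expect = np.exp(-0.5) + 0.5 * 6.0
        assert kernel_matrix(kern, A, B)[0, 0] == pytest.approx(expect)

    def test_rejects_non_finite_and_mismatch(self, kern2d):
        with pytest.raises(ValidationError):
            kernel_matrix(kern2d, np.array([[np.nan, 0.0]]), np.zeros((1, 2)))
        with pytest.raises(ValidationError):
            kernel_matrix(kern2d, np.zeros((1, 3)), np.zeros((1, 3)))

    def test_psd_on_random_inputs(self, kern2d):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(8, 2))
        w = np.linalg.eigvalsh(kernel_matrix(kern2d, A, A))
        assert w.min() > -1e-10

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValidationError):
            Kernel(SE_ARD, np.array([-1.0]), 1.0)
        with pytest.raises(ValidationError):
            Kernel(SE_ARD, np.array([1.0]), 0.0)
        with pytest.raises(ValidationError):
            Kernel("nope", np.array([1.0]), 1.0)


def _manual_model(kern, noise, X, y):
    return GPModel(
        kernel=kern, noise_variance=noise, train_inputs=X, train_targets=y,
        x_mean=np.zeros(X.shape[1]), x_sd=np.ones(X.shape[1]), y_mean=0.0,
        log_marginal_likelihood=np.nan,
    )


class TestLogMarginalLikelihood:
    def test_single_standard_normal_observation(self):
        kern = Kernel(SE_ARD, np.array([1.0]), 0.4)
        m = _manual_model(kern, 0.6, np.zeros((1, 1)), np.zeros(1))
        assert log_marginal_likelihood(m) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-9
        )

    def test_matches_dense_oracle_on_4_points(self, kern2d):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(4, 2)), rng.normal(size=4)
        m = _manual_model(kern2d, 0.3, X, y)
        _, _, lml = dense_gp_oracle(kern2d, 0.3, X, y, X[:1])
        assert log_marginal_likelihood(m) == pytest.approx(lml, rel=1e-10)

    def test_scaling_change_of_variables(self, kern2d):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(5, 2)), rng.normal(size=5)
        c = 3.7
        m1 = _manual_model(kern2d, 0.3, X, y)
        kern_scaled = Kernel(
            kern2d.variant, kern2d.length_scales, c**2 * kern2d.signal_variance
        )
        m2 = _manual_model(kern_scaled, c**2 * 0.3, X, c * y)
        diff = log_marginal_likelihood(m2) - log_marginal_likelihood(m1)
        assert diff == pytest.approx(-5 * np.log(c), rel=1e-9)


class TestPredict:
    def test_matches_dense_oracle(self, kern2d):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(5, 2)), rng.normal(size=5)
        Xs = rng.normal(size=(3, 2))
        m = _manual_model(kern2d, 0.25, X, y)
        p = predict_gp(m, Xs)
        mean, var, _ = dense_gp_oracle(kern2d, 0.25, X, y, Xs)
        np.testing.assert_allclose(p.mean, mean, rtol=1e-8)
        np.testing.assert_allclose(p.function_variance, var, rtol=1e-8, atol=1e-12)

    def test_far_query_reverts_to_prior(self, kern2d):
        rng = np.random.default_rng(5)
        X, y = rng.normal(size=(5, 2)), rng.normal(size=5)
        m = _manual_model(kern2d, 0.25, X, y)
        far = np.array([[100.0, 400.0]])  # >= 20 length-scales away
        p = predict_gp(m, far)
        assert p.mean[0] == pytest.approx(0.0, abs=1e-8)
        assert p.function_variance[0] == pytest.approx(1.7, rel=1e-8)

    def test_interpolates_training_point_at_tiny_noise(self, kern2d):
        rng = np.random.default_rng(6)
        X, y = rng.normal(size=(5, 2)), rng.normal(size=5)
        m = _manual_model(kern2d, 1e-12, X, y)
        p = predict_gp(m, X[2:3])
        assert p.mean[0] == pytest.approx(y[2], abs=1e-6)

    def test_extrapolation_variance_monotone_along_ray(self, kern2d):
        rng = np.random.default_rng(7)
        X, y = rng.normal(size=(8, 2)), rng.normal(size=8)
        m = _manual_model(kern2d, 0.3, X, y)
        direction = np.array([1.0, 1.0]) / np.sqrt(2)
        start = X.mean(axis=0) + 3.0 * direction  # outside the hull
        ts = np.linspace(0, 30, 40)
        var = predict_gp(m, start + ts[:, None] * direction).function_variance
        assert np.all(np.diff(var) >= -1e-10)

    def test_covariate_count_mismatch(self, kern2d):
        m = _manual_model(kern2d, 0.3, np.zeros((3, 2)), np.zeros(3))
        with pytest.raises(ValidationError):
            predict_gp(m, np.zeros((1, 3)))

    def test_duplicate_observation_never_increases_variance(self, kern2d):
        rng = np.random.default_rng(8)
        X, y = rng.normal(size=(6, 2)), rng.normal(size=6)
        Xs = rng.normal(size=(10, 2))
        m1 = _manual_model(kern2d, 0.3, X, y)
        X2 = np.vstack([X, X[0]])
        y2 = np.append(y, y[0])
        m2 = _manual_model(kern2d, 0.3, X2, y2)
        v1 = predict_gp(m1, Xs).function_variance
        v2 = predict_gp(m2, Xs).function_variance
        assert np.all(v2 <= v1 + 1e-10)


class TestFit:
    def test_recovers_noiseless_linear_function(self):
        rng = np.random.default_rng(10)
        X = np.sort(rng.uniform(0, 1, size=(40, 1)), axis=0)
        y = 2.0 * X[:, 0] + 1.0
        m = fit_gp(X, y, restarts=3, seed=0)
        q = np.linspace(0.2, 0.8, 7)[:, None]  # interior points
        p = predict_gp(m, q)
        np.testing.assert_allclose(p.mean, 2.0 * q[:, 0] + 1.0, rtol=0.01)

    def test_noise_variance_recovery_n500(self):
        # true noise variance 1.0; tolerance reflects sampling variability
        # of a variance estimate at n=500
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, size=(500, 1))
            y = np.sin(3.0 * X[:, 0]) + rng.normal(0, 1.0, 500)
            m = fit_gp(X, y, restarts=2, seed=seed)
            ratios.append(m.noise_variance)
        med = float(np.median(ratios))
        assert 0.8 <= med <= 1.25
        assert np.mean([(0.8 <= r <= 1.25) for r in ratios]) >= 0.8

    def test_irrelevant_covariate_down_weighted(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, size=(200, 2))
        y = np.sin(4.0 * X[:, 0]) + rng.normal(0, 0.1, 200)
        m = fit_gp(X, y, restarts=3, seed=1)
        ls = m.kernel.length_scales
        assert ls[1] / ls[0] >= 5.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, size=(30, 1))
        y = X[:, 0] + rng.normal(0, 0.3, 30)
        m1 = fit_gp(X, y, restarts=3, seed=7)
        m2 = fit_gp(X, y, restarts=3, seed=7)
        assert m1.log_marginal_likelihood == m2.log_marginal_likelihood
        assert np.array_equal(m1.kernel.length_scales, m2.kernel.length_scales)

    def test_zero_variance_response_rejected(self):
        X = np.linspace(0, 1, 10)[:, None]
        with pytest.raises(DegenerateResponseError):
            fit_gp(X, np.ones(10))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError):
            fit_gp(np.zeros((2, 1)), np.array([0.0, 1.0]))

    def test_linear_se_variant_fits(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 1, size=(50, 1))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.2, 50)
        m = fit_gp(X, y, kernel_variant="linear_se_ard", restarts=2, seed=0)
        p = predict_gp(m, np.array([[0.5]]))
        assert p.mean[0] == pytest.approx(1.5, abs=0.2)


class TestCalibrationAndStability:
    def test_null_predictive_calibration(self):
        """Standardized residuals on prior-simulated data pass a KS test
        against N(0,1) in >= 95% of seeded replicates."""
        kern = Kernel(SE_ARD, np.array([0.4]), 1.0)
        passes = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, size=(60, 1))
            K = kernel_matrix(kern, X, X) + 1e-10 * np.eye(60)
            f = np.linalg.cholesky(K) @ rng.normal(size=60)
            y = f + rng.normal(0, 0.5, 60)
            m = _manual_model(kern, 0.25, X[:40], y[:40])
            p = predict_gp(m, X[40:])
            z = (y[40:] - p.mean) / np.sqrt(p.function_variance + 0.25)
            if stats.kstest(z, "norm").pvalue > 0.01:
                passes += 1
        assert passes / n_rep >= 0.95

    def test_jitter_invariance_of_mean(self, kern2d):
        rng = np.random.default_rng(14)
        X, y = rng.normal(size=(10, 2)), rng.normal(size=10)
        Xs = rng.normal(size=(5, 2))
        base = _manual_model(kern2d, 0.3, X, y)
        base._ensure_cache()
        means = [predict_gp(base, Xs).mean]
        for jit in (1e-10, 1e-9):
            m = _manual_model(kern2d, 0.3 + jit, X, y)
            means.append(predict_gp(m, Xs).mean)
        for other in means[1:]:
            np.testing.assert_allclose(means[0], other, atol=1e-6)

    def test_matches_sklearn_reference(self):
        """Independent cross-check: identical fixed hyperparameters give the
        same posterior as scikit-learn's GP regressor."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(15)
        X, y = rng.normal(size=(12, 2)), rng.normal(size=12)
        Xs = rng.normal(size=(4, 2))
        kern = Kernel(SE_ARD, np.array([0.8, 1.3]), 1.4)
        m = _manual_model(kern, 0.2, X, y)
        p = predict_gp(m, Xs)

        sk = GaussianProcessRegressor(
            kernel=ConstantKernel(1.4, "fixed") * RBF([0.8, 1.3], "fixed"),
            alpha=0.2, optimizer=None,
        ).fit(X, y)
        mean, std = sk.predict(Xs, return_std=True)
        np.testing.assert_allclose(p.mean, mean, rtol=1e-7, atol=1e-9)
        np.testing.assert_allclose(
            np.sqrt(p.function_variance), std, rtol=1e-6, atol=1e-8
        )
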