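"""Exact single-output Gaussian-process regression with ARD relevance weighting.

This is the per-location workhorse of the normative model: a zero-mean GP
prior over functions of the clinical covariates, a squared-exponential
kernel with one length-scale per covariate (automatic relevance
determination, so irrelevant covariates are down-weighted by learning long
length-scales), Gaussian observation noise, and type-II maximum-likelihood
hyperparameter estimation in log-space with seeded multi-restart
optimization.

Two variances are kept strictly separate throughout:

* ``function_variance`` — the noise-free posterior variance of the latent
  function at a query point (sigma_ij^2 in the deviation Z-score), which
  grows when extrapolating away from the training covariates;
* ``noise_variance`` — the learned observation-noise variance of the
  normative cohort at this location (sigma_nj^2).

The deviation score downstream sums the two explicitly, so neither is ever
folded into the other here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

log = logging.getLogger("normap")

SE_ARD = "se_ard"
LINEAR_SE_ARD = "linear_se_ard"
KERNEL_VARIANTS = (SE_ARD, LINEAR_SE_ARD)

#: multiplicative jitter ladder applied to the mean kernel diagonal when a
#: Cholesky factorization fails; exhausting it is an error, never silent.
JITTER_LADDER = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class DegenerateResponseError(ValidationError):
    """Raised when the response vector has zero variance (constant y)."""


class FitFailureError(RuntimeError):
    """Raised when every optimizer restart fails to produce a finite fit."""


class NumericalError(RuntimeError):
    """Raised when the kernel matrix is not positive definite after the
    full jitter ladder."""


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Kernel:
    """ARD kernel hyperparameters.

    Parameters
    ----------
    variant
        ``"se_ard"`` for the squared-exponential ARD kernel, or
        ``"linear_se_ard"`` for its sum with a homogeneous linear kernel.
    length_scales
        One strictly positive length-scale per covariate, in covariate
        units. A long length-scale marks a covariate as irrelevant.
    signal_variance
        Prior variance of the latent function, in response units squared.
    linear_variance
        Variance of the linear component (``linear_se_ard`` only).
    """

    variant: str
    length_scales: np.ndarray
    signal_variance: float
    linear_variance: float = 0.0

    def __post_init__(self):
        ls = np.atleast_1d(np.asarray(self.length_scales, dtype=float))
        object.__setattr__(self, "length_scales", ls)
        if self.variant not in KERNEL_VARIANTS:
            raise ValidationError(f"unknown kernel variant {self.variant!r}")
        if not np.all(np.isfinite(ls)) or np.any(ls <= 0):
            raise ValidationError("length_scales must be positive and finite")
        if not np.isfinite(self.signal_variance) or self.signal_variance <= 0:
            raise ValidationError("signal_variance must be positive and finite")
        if self.variant == LINEAR_SE_ARD and self.linear_variance <= 0:
            raise ValidationError("linear_variance must be positive for linear_se_ard")

    @property
    def n_covariates(self) -> int:
        return self.length_scales.shape[0]


def _check_rows(kernel: Kernel, A: np.ndarray, name: str) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[1] != kernel.n_covariates:
        raise ValidationError(
            f"{name} has {A.shape[1]} covariates, kernel expects {kernel.n_covariates}"
        )
    if not np.all(np.isfinite(A)):
        raise ValidationError(f"non-finite covariate values in {name}")
    return A


def kernel_matrix(kernel: Kernel, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cross-covariance matrix ``k(A[a], B[b])`` under the kernel.

    Symmetric positive semi-definite when ``A is B``.
    """
    A = _check_rows(kernel, A, "A")
    B = _check_rows(kernel, B, "B")
    As = A / kernel.length_scales
    Bs = B / kernel.length_scales
    sq = (
        np.sum(As**2, axis=1)[:, None]
        + np.sum(Bs**2, axis=1)[None, :]
        - 2.0 * As @ Bs.T
    )
    np.maximum(sq, 0.0, out=sq)
    K = kernel.signal_variance * np.exp(-0.5 * sq)
    if kernel.variant == LINEAR_SE_ARD:
        K = K + kernel.linear_variance * (A @ B.T)
    return K


def _kernel_diag(kernel: Kernel, A: np.ndarray) -> np.ndarray:
    d = np.full(A.shape[0], kernel.signal_variance)
    if kernel.variant == LINEAR_SE_ARD:
        d = d + kernel.linear_variance * np.sum(A * A, axis=1)
    return d


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class GPModel:
    """A fitted GP: kernel + noise hyperparameters and cached training state.

    ``train_inputs`` are stored standardized (when ``x_mean``/``x_sd`` are
    set) and ``train_targets`` centered; predictions restore the offsets.
    """

    kernel: Kernel
    noise_variance: float
    train_inputs: np.ndarray
    train_targets: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    log_marginal_likelihood: float
    jitter: float = 0.0
    n_restarts_used: int = 0
    converged: bool = True
    # cached Cholesky factor of K + noise*I (+ jitter) and K^{-1} y
    _chol: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    def _ensure_cache(self):
        if self._chol is None:
            K = kernel_matrix(self.kernel, self.train_inputs, self.train_inputs)
            K[np.diag_indices_from(K)] += self.noise_variance
            self._chol, self.jitter = _chol_with_jitter(K)
            self._alpha = cho_solve((self._chol, True), self.train_targets)


def _chol_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky of K, escalating diagonal jitter along the ladder."""
    scale = float(np.mean(np.diag(K)))
    for j in JITTER_LADDER:
        try:
            L = cholesky(K + j * scale * np.eye(K.shape[0]), lower=True)
            return L, j * scale
        except np.linalg.LinAlgError:
            continue
    raise NumericalError(
        "kernel matrix not positive definite after jitter ladder "
        f"(max jitter {JITTER_LADDER[-1] * scale:.3g})"
    )


# ---------------------------------------------------------------------------
# Marginal likelihood and gradients (log-parameter space)
# ---------------------------------------------------------------------------


def _theta_to_kernel(theta: np.ndarray, variant: str, D: int) -> tuple[Kernel, float]:
    ls = np.exp(theta[:D])
    sv = float(np.exp(theta[D]))
    if variant == LINEAR_SE_ARD:
        lv = float(np.exp(theta[D + 1]))
        nv = float(np.exp(theta[D + 2]))
        return Kernel(variant, ls, sv, lv), nv
    nv = float(np.exp(theta[D + 1]))
    return Kernel(variant, ls, sv), nv


#: log-parameter box for the optimizer; wide enough to be vacuous for any
#: standardized problem while keeping exp() finite
LOG_PARAM_BOUND = 25.0


def _nll_and_grad(theta, X, y, variant):
    n, D = X.shape
    theta = np.clip(theta, -LOG_PARAM_BOUND, LOG_PARAM_BOUND)
    kern, nv = _theta_to_kernel(theta, variant, D)
    Xs = X / kern.length_scales
    sq = (
        np.sum(Xs**2, axis=1)[:, None]
        + np.sum(Xs**2, axis=1)[None, :]
        - 2.0 * Xs @ Xs.T
    )
    np.maximum(sq, 0.0, out=sq)
    Kse = kern.signal_variance * np.exp(-0.5 * sq)
    K = Kse.copy()
    if variant == LINEAR_SE_ARD:
        Klin = kern.linear_variance * (X @ X.T)
        K += Klin
    K[np.diag_indices_from(K)] += nv
    try:
        L, _ = _chol_with_jitter(K)
    except NumericalError:
        return np.inf, np.zeros_like(theta)
    alpha = cho_solve((L, True), y)
    lml = (
        -0.5 * float(y @ alpha)
        - float(np.sum(np.log(np.diag(L))))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    # M = alpha alpha^T - K^{-1}; d(lml)/dtheta_i = 0.5 tr(M dK/dtheta_i)
    Kinv = cho_solve((L, True), np.eye(n))
    M = np.outer(alpha, alpha) - Kinv
    grad = np.empty_like(theta)
    for d in range(D):
        diff = X[:, d][:, None] - X[:, d][None, :]
        dK = Kse * (diff**2 / kern.length_scales[d] ** 2)
        grad[d] = 0.5 * np.sum(M * dK)
    grad[D] = 0.5 * np.sum(M * Kse)
    if variant == LINEAR_SE_ARD:
        grad[D + 1] = 0.5 * np.sum(M * Klin)
        grad[D + 2] = 0.5 * nv * np.trace(M)
    else:
        grad[D + 1] = 0.5 * nv * np.trace(M)
    return -lml, -grad


def log_marginal_likelihood(model: GPModel) -> float:
    """Exact Gaussian log marginal likelihood of the training targets."""
    model._ensure_cache()
    y = model.train_targets
    n = y.shape[0]
    return (
        -0.5 * float(y @ model._alpha)
        - float(np.sum(np.log(np.diag(model._chol))))
        - 0.5 * n * np.log(2.0 * np.pi)
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _median_nn_distance(Xs: np.ndarray) -> float:
    """Median nearest-neighbour Euclidean distance between input rows."""
    n = Xs.shape[0]
    if n > 600:  # O(n^2); subsample for very large fits
        idx = np.linspace(0, n - 1, 600).astype(int)
        Xs = Xs[idx]
        n = 600
    sq = (
        np.sum(Xs**2, axis=1)[:, None]
        + np.sum(Xs**2, axis=1)[None, :]
        - 2.0 * Xs @ Xs.T
    )
    np.fill_diagonal(sq, np.inf)
    nn = np.sqrt(np.maximum(sq.min(axis=1), 0.0))
    return float(np.median(nn))


def fit_gp(
    X: np.ndarray,
    y: np.ndarray,
    kernel_variant: str = SE_ARD,
    restarts: int = 5,
    seed: int = 0,
    standardize: bool = True,
    init: dict | None = None,
    maxiter: int = 200,
    length_scale_floor: float | None = None,
) -> GPModel:
    """Fit a GP by type-II maximum likelihood with seeded restarts.

    Hyperparameters are optimized in log space with analytic gradients
    (L-BFGS-B). Restart ``r > 0`` perturbs the data-driven initialization
    by log-normal jitter (sd 0.5 in log space) drawn from a generator
    seeded with ``seed``; the restart with the highest log marginal
    likelihood wins, so the fit is deterministic given ``seed``.

    Initialization (before optional ``init`` overrides): length-scales at
    the per-covariate standard deviation of the inputs, signal variance at
    var(y), noise variance at 0.1 var(y).

    Length-scales are bounded below at the median nearest-neighbour
    spacing of the (standardized) inputs unless ``length_scale_floor``
    overrides it (0 disables). Structure finer than the data's resolution
    is unidentifiable, and maximum-likelihood fits that enter that regime
    interpolate observation noise — the noise variance collapses to zero
    and held-out deviation scores blow up. The floor removes exactly that
    degenerate family of optima and nothing else.

    Raises
    ------
    DegenerateResponseError
        if ``y`` has zero variance — callers may fall back to a constant
        model.
    FitFailureError
        if no restart yields a finite optimum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y have different numbers of observations")
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 observations to fit a GP")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in training data")
    vy = float(np.var(y))
    if vy <= 0.0:
        raise DegenerateResponseError("response vector has zero variance")

    n, D = X.shape
    if standardize:
        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0)
        x_sd = np.where(x_sd > 0, x_sd, 1.0)
    else:
        x_mean = np.zeros(D)
        x_sd = np.ones(D)
    Xs = (X - x_mean) / x_sd
    y_mean = float(y.mean())
    yc = y - y_mean

    if length_scale_floor is None:
        ls_floor = _median_nn_distance(Xs)
    else:
        ls_floor = float(length_scale_floor)
    ls_floor = max(ls_floor, np.exp(-LOG_PARAM_BOUND + 1))

    ls0 = np.maximum(np.where(Xs.std(axis=0) > 0, Xs.std(axis=0), 1.0), ls_floor)
    sv0 = vy
    nv0 = 0.1 * vy
    lv0 = 0.1 * vy
    init = init or {}
    ls0 = np.asarray(init.get("length_scales", ls0), dtype=float)
    sv0 = float(init.get("signal_variance", sv0))
    nv0 = float(init.get("noise_variance", nv0))
    lv0 = float(init.get("linear_variance", lv0))
    if kernel_variant == LINEAR_SE_ARD:
        theta0 = np.log(np.concatenate([ls0, [sv0, lv0, nv0]]))
    else:
        theta0 = np.log(np.concatenate([ls0, [sv0, nv0]]))

    bounds = [(np.log(ls_floor), LOG_PARAM_BOUND)] * D + [
        (-LOG_PARAM_BOUND, LOG_PARAM_BOUND)
    ] * (theta0.size - D)
    lower = np.array([b[0] for b in bounds])
    rng = np.random.default_rng(seed)
    best = None
    n_ok = 0
    for r in range(max(1, restarts)):
        start = theta0 if r == 0 else theta0 + rng.normal(0.0, 0.5, size=theta0.shape)
        res = minimize(
            _nll_and_grad,
            np.clip(start, np.maximum(lower, -LOG_PARAM_BOUND + 1),
                    LOG_PARAM_BOUND - 1),
            args=(Xs, yc, kernel_variant),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter},
        )
        if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitFailureError(
            f"all {max(1, restarts)} restarts failed to converge "
            f"(last status: {res.message!r})"
        )

    kern, nv = _theta_to_kernel(best.x, kernel_variant, D)
    model = GPModel(
        kernel=kern,
        noise_variance=nv,
        train_inputs=Xs,
        train_targets=yc,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        log_marginal_likelihood=-float(best.fun),
        n_restarts_used=n_ok,
        converged=bool(best.success),
    )
    model._ensure_cache()
    return model


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Prediction:
    """Posterior predictive summary at query points.

    ``mean`` is the expected response (yhat_ij); ``function_variance`` the
    noise-free posterior variance of the latent function (sigma_ij^2);
    ``noise_variance`` the model's learned observation noise (sigma_nj^2),
    carried along so downstream code never has to re-pair them.
    """

    mean: np.ndarray
    function_variance: np.ndarray
    noise_variance: float


def predict_gp(model: GPModel, Xstar: np.ndarray) -> Prediction:
    """Exact GP posterior mean and noise-free function variance at Xstar."""
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if Xstar.shape[1] != model.kernel.n_covariates:
        raise ValidationError(
            f"Xstar has {Xstar.shape[1]} covariates, model expects "
            f"{model.kernel.n_covariates}"
        )
    model._ensure_cache()
    Xq = (Xstar - model.x_mean) / model.x_sd
    Ks = kernel_matrix(model.kernel, model.train_inputs, Xq)
    mean = Ks.T @ model._alpha + model.y_mean
    v = solve_triangular(model._chol, Ks, lower=True)
    fvar = _kernel_diag(model.kernel, Xq) - np.sum(v * v, axis=0)
    np.maximum(fvar, 0.0, out=fvar)
    return Prediction(mean=mean, function_variance=fvar,
                      noise_variance=model.noise_variance)
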