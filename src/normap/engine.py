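"""Mass-univariate normative model estimation and deviation scoring.

Each response location (voxel, vertex, or region — a "brainordinate") is
modelled independently by a GP linking the clinical covariates to the
response. Estimation runs under grouped k-fold cross-validation so that a
subject's own response never informs the prediction it is scored against,
and so that related subjects (families) never straddle a train/test split.

The deviation of subject i at location j is the Z-score

    z_ij = (y_ij - yhat_ij) / sqrt(sigma_ij^2 + sigma_nj^2)

combining the prediction error, the predictive (function) variance of the
test point, and the learned normative noise variance. The matrix of z_ij
is the subject's normative probability map (NPM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .gp import (
    DegenerateResponseError,
    FitFailureError,
    GPModel,
    NumericalError,
    ValidationError,
    fit_gp,
    predict_gp,
)

log = logging.getLogger("normap")

#: abort a run when more than this fraction of locations fail to fit
MAX_FAILED_LOCATION_FRACTION = 0.05


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class CovariateTable:
    """Subjects x covariates design matrix with aligned identifiers."""

    values: np.ndarray
    subject_ids: list[str]
    covariate_names: list[str]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.subject_ids), len(self.covariate_names)):
            raise ValidationError("covariate matrix shape does not match labels")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("duplicate subject_ids in covariate table")
        if self.values.shape[1] < 1:
            raise ValidationError("need at least one covariate")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("missing or non-finite covariate values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class ResponseMatrix:
    """Subjects x locations response matrix, the mass-univariate target."""

    values: np.ndarray
    subject_ids: list[str]
    location_ids: list[str]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.subject_ids), len(self.location_ids)):
            raise ValidationError("response matrix shape does not match labels")
        if len(set(self.location_ids)) != len(self.location_ids):
            raise ValidationError("duplicate location_ids")

    @property
    def n_locations(self) -> int:
        return self.values.shape[1]


def check_alignment(X: CovariateTable, Y: ResponseMatrix) -> None:
    """Refuse silently inconsistent inputs with a diff-style report."""
    if X.subject_ids == Y.subject_ids:
        return
    only_x = [s for s in X.subject_ids if s not in set(Y.subject_ids)]
    only_y = [s for s in Y.subject_ids if s not in set(X.subject_ids)]
    lines = ["subject IDs differ between covariates and responses:"]
    for s in only_x[:10]:
        lines.append(f"  - {s} (covariates only)")
    for s in only_y[:10]:
        lines.append(f"  + {s} (responses only)")
    if not (only_x or only_y):
        lines.append("  (same sets, different order)")
    raise ValidationError("\n".join(lines))


@dataclass(frozen=True)
class FoldAssignment:
    """Per-subject fold indices honouring group (family) atomicity."""

    fold_index: np.ndarray
    k: int
    group_ids: list[str] | None = None

    def train_test(self, f: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.fold_index == f
        return ~test, test


def grouped_kfold(group_ids, k: int, seed: int = 0) -> FoldAssignment:
    """Assign whole groups to folds, balancing fold sizes greedily.

    Groups are visited largest-first (ties broken by a seeded shuffle) and
    each is placed in the currently smallest fold, so every family stays
    within a single fold and fold sizes differ by at most the largest
    group size. Deterministic given ``seed``.
    """
    group_ids = [str(g) for g in group_ids]
    if k < 2:
        raise ValidationError("k must be >= 2")
    uniq = sorted(set(group_ids))
    if len(uniq) < k:
        raise ValidationError(
            f"only {len(uniq)} distinct groups for k={k} folds"
        )
    rng = np.random.default_rng(seed)
    sizes = {g: 0 for g in uniq}
    for g in group_ids:
        sizes[g] += 1
    order = list(uniq)
    rng.shuffle(order)
    order.sort(key=lambda g: -sizes[g])  # stable: seeded order breaks ties
    fold_of_group: dict[str, int] = {}
    fold_sizes = np.zeros(k, dtype=int)
    for g in order:
        f = int(np.argmin(fold_sizes))
        fold_of_group[g] = f
        fold_sizes[f] += sizes[g]
    fold_index = np.array([fold_of_group[g] for g in group_ids], dtype=int)
    return FoldAssignment(fold_index=fold_index, k=k, group_ids=group_ids)


# ---------------------------------------------------------------------------
# Model set / predictions
# ---------------------------------------------------------------------------


@dataclass
class NormativeModelSet:
    """Per-location fitted GP models (fit on all data) plus diagnostics.

    ``failed`` flags locations whose fit raised; they are excluded from
    downstream tail statistics rather than imputed.
    """

    models: list[GPModel | None]
    location_ids: list[str]
    failed: np.ndarray
    log_marginal_likelihoods: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def noise_variances(self) -> np.ndarray:
        return np.array(
            [m.noise_variance if m is not None else np.nan for m in self.models]
        )


@dataclass
class CVPredictions:
    """Cross-validated held-out predictions per subject x location.

    ``noise_variance`` is per cell because each subject's prediction comes
    from the model of the fold that held the subject out.
    """

    mean: np.ndarray
    function_variance: np.ndarray
    noise_variance: np.ndarray
    provenance: str = "cross-validated"


@dataclass
class NPM:
    """Normative probability map: subjects x locations Z-scores."""

    z: np.ndarray
    subject_ids: list[str]
    location_ids: list[str]
    provenance: str = "cross-validated"


def _fit_seed(base: int, location: int, fold: int) -> int:
    return int((base * 1000003 + location * 9176 + fold * 13) % (2**31 - 1))


def estimate_normative(
    X: CovariateTable,
    Y: ResponseMatrix,
    folds: FoldAssignment,
    gp_config: dict | None = None,
    final_fit: bool = True,
) -> tuple[NormativeModelSet, CVPredictions]:
    """Fit per-location normative GPs under grouped cross-validation.

    For every fold, models are trained on the training subjects only and
    predictions (mean, function variance, and the fold's learned noise
    variance) are produced for the held-out subjects. A final model per
    location is also refit on all subjects for chart/visualization use
    (skipped with ``final_fit=False`` when only the cross-validated
    deviation scores are needed).

    Per-location fit failures are logged and flagged, not fatal; the run
    aborts if more than 5% of locations fail.
    """
    check_alignment(X, Y)
    cfg = {"kernel_variant": "se_ard", "restarts": 2, "seed": 0, "maxiter": 200}
    cfg.update(gp_config or {})
    base_seed = int(cfg.pop("seed"))
    n, L = Y.values.shape
    mean = np.full((n, L), np.nan)
    fvar = np.full((n, L), np.nan)
    nvar = np.full((n, L), np.nan)
    models: list[GPModel | None] = [None] * L
    failed = np.zeros(L, dtype=bool)
    lmls = np.full(L, np.nan)

    for j in range(L):
        y = Y.values[:, j]
        try:
            for f in range(folds.k):
                tr, te = folds.train_test(f)
                m = fit_gp(
                    X.values[tr], y[tr], seed=_fit_seed(base_seed, j, f), **cfg
                )
                pred = predict_gp(m, X.values[te])
                mean[te, j] = pred.mean
                fvar[te, j] = pred.function_variance
                nvar[te, j] = pred.noise_variance
            if final_fit:
                full = fit_gp(
                    X.values, y, seed=_fit_seed(base_seed, j, folds.k), **cfg
                )
                models[j] = full
                lmls[j] = full.log_marginal_likelihood
        except (DegenerateResponseError, FitFailureError, NumericalError) as e:
            failed[j] = True
            mean[:, j] = np.nan
            fvar[:, j] = np.nan
            nvar[:, j] = np.nan
            log.warning("location %s failed to fit: %s", Y.location_ids[j], e)

    frac = failed.mean()
    if frac > MAX_FAILED_LOCATION_FRACTION:
        raise FitFailureError(
            f"{failed.sum()}/{L} locations failed to fit "
            f"({100 * frac:.1f}% > {100 * MAX_FAILED_LOCATION_FRACTION:.0f}%)"
        )
    model_set = NormativeModelSet(
        models=models,
        location_ids=list(Y.location_ids),
        failed=failed,
        log_marginal_likelihoods=lmls,
        config={**cfg, "seed": base_seed, "k": folds.k},
    )
    preds = CVPredictions(mean=mean, function_variance=fvar, noise_variance=nvar)
    return model_set, preds


def compute_npm(Y: ResponseMatrix, preds: CVPredictions) -> NPM:
    """Elementwise deviation Z-scores from held-out predictions.

    z = (y - yhat) / sqrt(function_variance + noise_variance); cells at
    flagged (NaN-predicted) locations stay NaN.
    """
    if preds.mean.shape != Y.values.shape:
        raise ValidationError("prediction and response shapes differ")
    total = preds.function_variance + preds.noise_variance
    bad = np.isfinite(total) & (total <= 0)
    if np.any(bad):
        j = int(np.argwhere(bad.any(axis=0)).ravel()[0])
        raise NumericalError(
            f"non-positive total variance at location {Y.location_ids[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        z = (Y.values - preds.mean) / np.sqrt(total)
    return NPM(
        z=z,
        subject_ids=list(Y.subject_ids),
        location_ids=list(Y.location_ids),
        provenance=preds.provenance,
    )


def smse(true, predicted, baseline_variance: float) -> float:
    """Standardized mean squared error: MSE / variance of the test targets.

    Below 1 means the model predicts better than the (training) mean;
    callers average across folds.
    """
    true = np.asarray(true, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if true.shape != predicted.shape or true.size < 2:
        raise ValidationError("need equal-length vectors with >= 2 entries")
    if not baseline_variance > 0:
        raise ValidationError("baseline_variance must be > 0")
    return float(np.mean((true - predicted) ** 2) / baseline_variance)


def cv_smse(Y: ResponseMatrix, preds: CVPredictions, folds: FoldAssignment) -> np.ndarray:
    """Per-location SMSE averaged across cross-validation folds."""
    L = Y.n_locations
    out = np.full(L, np.nan)
    for j in range(L):
        if np.all(np.isnan(preds.mean[:, j])):
            continue
        vals = []
        for f in range(folds.k):
            _, te = folds.train_test(f)
            yt = Y.values[te, j]
            bv = float(np.var(yt, ddof=1))
            if bv <= 0:
                continue
            vals.append(smse(yt, preds.mean[te, j], bv))
        out[j] = np.mean(vals) if vals else np.nan
    return out


def run_pipeline(
    X: CovariateTable,
    Y: ResponseMatrix,
    group_ids,
    k: int = 10,
    seed: int = 0,
    gp_config: dict | None = None,
    final_fit: bool = True,
) -> tuple[NormativeModelSet, CVPredictions, NPM, FoldAssignment]:
    """Convenience wrapper: grouped folds -> normative fit -> NPM."""
    folds = grouped_kfold(group_ids, k=k, seed=seed)
    cfg = dict(gp_config or {})
    cfg.setdefault("seed", seed)
    model_set, preds = estimate_normative(X, Y, folds, cfg, final_fit=final_fit)
    npm = compute_npm(Y, preds)
    return model_set, preds, npm, folds


# ---------------------------------------------------------------------------
# Centile surfaces ("growth charts")
# ---------------------------------------------------------------------------


def centile_surface(
    model_set: NormativeModelSet, grid: np.ndarray, centiles
) -> np.ndarray:
    """Normative centile values on a covariate grid.

    Returns an array (locations, grid points, centiles) where centile c is
    mean + Phi^{-1}(c) * sqrt(function_variance + noise_variance). Bands
    are non-crossing by construction. Failed locations yield NaN.
    """
    centiles = np.asarray(centiles, dtype=float)
    if np.any(centiles <= 0) or np.any(centiles >= 1):
        raise ValidationError("centiles must lie strictly in (0, 1)")
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    L = len(model_set.models)
    out = np.full((L, grid.shape[0], centiles.size), np.nan)
    zq = norm.ppf(centiles)
    for j, m in enumerate(model_set.models):
        if m is None:
            continue
        pred = predict_gp(m, grid)
        sd = np.sqrt(pred.function_variance + pred.noise_variance)
        out[j] = pred.mean[:, None] + sd[:, None] * zq[None, :]
    return out


def covariate_grid(X: CovariateTable, points_per_axis: int = 50) -> np.ndarray:
    """Rectangular grid spanning the observed covariate ranges."""
    axes = [
        np.linspace(c.min(), c.max(), points_per_axis) for c in X.values.T
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def principal_axis_anchors(
    X: CovariateTable, n_anchors: int = 5, baseline: np.ndarray | None = None
) -> np.ndarray:
    """Anchor points along the first principal axis of the covariates.

    Reference points for chart-style visualization: equally spaced along
    the leading principal direction, measured from a baseline point
    (default: the covariate mean), spanning the range of the data's
    projections onto that axis.
    """
    V = X.values
    mu = V.mean(axis=0)
    _, _, vt = np.linalg.svd(V - mu, full_matrices=False)
    axis = vt[0]
    base = mu if baseline is None else np.asarray(baseline, dtype=float)
    proj = (V - base) @ axis
    ts = np.linspace(proj.min(), proj.max(), n_anchors)
    return base + ts[:, None] * axis[None, :]
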