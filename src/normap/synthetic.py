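"""Synthetic cohorts with the structure the normative model assumes.

The generator emulates a reference cohort like the one the method targets:
bounded, skewed trait covariates (area-under-curve-style discounting
scores in [0, 1], a pair of correlated measures by default); many response
locations of which a fraction carry a smooth nonlinear covariate-response
surface and the rest are pure noise; family structure (sibling groups
share a random intercept per location, so grouped cross-validation
demonstrably matters); and planted outlier subjects whose responses are
shifted away from the normative surface at a sparse idiosyncratic set of
locations.

Symptom scores can be generated under several mechanisms: ``null`` (no
relation to anything), ``extreme-of-normal`` (symptoms track the
subject's position along the covariate principal axis — high symptoms
within the normal spectrum), ``deviance-linked`` (symptoms track the
planted deviation magnitude), or ``mixture`` (both subpopulations
coexist). The mixture is the scenario in which only the deviance-linked
subjects should light up in deviance-symptom tail correlations while the
extreme-of-normal subjects should pass every outlier test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import CovariateTable, ResponseMatrix
from .gp import ValidationError

TRUTH_SCHEMA_VERSION = 1

SYMPTOM_MODELS = ("null", "extreme-of-normal", "deviance-linked", "mixture")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults describe the desk-scale reference condition: 500 subjects x
    2000 locations, two correlated bounded covariates, 30% of locations
    carrying signal with unit signal and noise standard deviation, family
    sizes 1-3, and 5% outlier subjects shifted by 4 total SD at 1% of
    locations.
    """

    n_subjects: int = 500
    n_covariates: int = 2
    n_locations: int = 2000
    signal_fraction: float = 0.3
    signal_sd: float = 1.0
    noise_sd: float = 1.0
    family_effect_sd: float = 0.3
    family_size_probs: tuple = (0.55, 0.30, 0.15)  # sizes 1, 2, 3
    outlier_fraction: float = 0.05
    outlier_n_locations: int = 20
    outlier_magnitude: float = 4.0
    outlier_magnitude_spread: float = 0.9
    outlier_sign: str = "negative"
    symptom_model: str = "mixture"
    covariate_corr: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("signal_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.outlier_n_locations > self.n_locations:
            raise ValidationError("outlier_n_locations exceeds n_locations")
        if self.symptom_model not in SYMPTOM_MODELS:
            raise ValidationError(f"symptom_model must be one of {SYMPTOM_MODELS}")
        if self.outlier_sign not in ("positive", "negative", "mixed"):
            raise ValidationError("outlier_sign must be positive/negative/mixed")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


@dataclass
class CohortTruth:
    """Ground truth behind a generated cohort (for validation, not fitting)."""

    schema_version: int
    spec: dict
    signal_locations: list[int]
    noise_sd: float
    total_sd: list[float]
    outlier_subjects: list[str]
    outlier_locations: dict
    outlier_shifts: dict
    symptom_model: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass
class Cohort:
    covariates: CovariateTable
    responses: ResponseMatrix
    group_ids: list[str]
    symptoms: np.ndarray
    truth: CohortTruth
    #: true normative surface per subject x location (0 at noise locations);
    #: kept in memory for validation, not serialized with fixtures
    surface: np.ndarray | None = None


# AUC-like marginals: one steep-discounting skewed score, one milder one
_BETA_PARAMS = [(1.5, 4.5), (2.3, 2.7), (2.0, 2.0)]


def _draw_covariates(rng, n, d, corr):
    cov = np.full((d, d), corr) + (1 - corr) * np.eye(d)
    latent = rng.multivariate_normal(np.zeros(d), cov, size=n)
    from scipy.stats import beta, norm

    u = norm.cdf(latent)
    out = np.empty_like(u)
    for j in range(d):
        a, b = _BETA_PARAMS[j % len(_BETA_PARAMS)]
        out[:, j] = beta.ppf(u[:, j], a, b)
    return out


def _smooth_surface(rng, Xz):
    """Random low-order polynomial surface on standardized covariates."""
    n, d = Xz.shape
    feats = [Xz[:, a] for a in range(d)]
    for a in range(d):
        feats.append(Xz[:, a] ** 2)
        feats.append(Xz[:, a] ** 3)
    for a in range(d):
        for b in range(a + 1, d):
            feats.append(Xz[:, a] * Xz[:, b])
    F = np.column_stack(feats)
    w = rng.normal(0.0, 1.0, size=F.shape[1]) / np.sqrt(F.shape[1])
    f = F @ w
    f = f - f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort deterministically from ``spec`` (incl. its seed)."""
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_subjects, spec.n_locations

    X = _draw_covariates(rng, n, spec.n_covariates, spec.covariate_corr)
    subject_ids = [f"S{i:04d}" for i in range(n)]
    covariate_names = [f"auc{j}" for j in range(spec.n_covariates)]
    location_ids = [f"loc{j:05d}" for j in range(L)]

    # family structure: sibling groups of size 1-3
    sizes = []
    while sum(sizes) < n:
        sizes.append(int(rng.choice([1, 2, 3], p=spec.family_size_probs)))
    group_ids = []
    fam = 0
    for s in sizes:
        group_ids.extend([f"F{fam:04d}"] * s)
        fam += 1
    group_ids = group_ids[:n]
    n_fam = len(set(group_ids))
    fam_index = np.array([int(g[1:]) for g in group_ids])

    n_signal = int(round(spec.signal_fraction * L))
    signal_locs = np.sort(rng.choice(L, size=n_signal, replace=False))
    is_signal = np.zeros(L, dtype=bool)
    is_signal[signal_locs] = True

    Xz = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Y = np.empty((n, L))
    surface = np.zeros((n, L))
    for j in range(L):
        if is_signal[j]:
            surface[:, j] = spec.signal_sd * _smooth_surface(rng, Xz)
        fam_fx = rng.normal(0.0, spec.family_effect_sd, size=n_fam)[fam_index]
        Y[:, j] = surface[:, j] + fam_fx + rng.normal(0.0, spec.noise_sd, size=n)

    total_sd = np.sqrt(
        (spec.signal_sd**2) * is_signal
        + spec.family_effect_sd**2
        + spec.noise_sd**2
    )

    # planted outliers: sparse idiosyncratic additive shifts
    n_out = int(round(spec.outlier_fraction * n))
    out_idx = np.sort(rng.choice(n, size=n_out, replace=False))
    outlier_locations: dict[str, list[int]] = {}
    outlier_shifts: dict[str, float] = {}
    injected = np.zeros(n)  # per-subject injected magnitude in SD units
    for i in out_idx:
        locs = rng.choice(L, size=spec.outlier_n_locations, replace=False)
        # log-normal spread gives the injected magnitudes a heavy right
        # tail, so the most deviant subjects are spread out rather than
        # piled at a ceiling (spread=0 plants the magnitude exactly)
        s = spec.outlier_magnitude_spread
        mag = spec.outlier_magnitude * (np.exp(rng.normal(0.0, s)) if s > 0 else 1.0)
        if spec.outlier_sign == "positive":
            sign = 1.0
        elif spec.outlier_sign == "negative":
            sign = -1.0
        else:
            sign = float(rng.choice([-1.0, 1.0]))
        Y[i, locs] += sign * mag * total_sd[locs]
        sid = subject_ids[i]
        outlier_locations[sid] = [int(x) for x in np.sort(locs)]
        outlier_shifts[sid] = float(sign * mag)
        injected[i] = mag

    # symptoms
    mu = X.mean(axis=0)
    _, _, vt = np.linalg.svd(X - mu, full_matrices=False)
    pc1 = (X - mu) @ vt[0]
    pc1 = (pc1 - pc1.mean()) / pc1.std()
    eps = rng.normal(0.0, 1.0, size=n)
    is_outlier = np.zeros(n, dtype=bool)
    is_outlier[out_idx] = True
    if spec.symptom_model == "null":
        symptoms = eps
    elif spec.symptom_model == "extreme-of-normal":
        symptoms = 1.5 * np.abs(pc1) + 0.5 * eps
    elif spec.symptom_model == "deviance-linked":
        symptoms = injected + 0.15 * eps
    else:
        # mixture: two distinct routes to high symptoms — subjects at the
        # extreme of the normal covariate spectrum, and subjects whose
        # responses idiosyncratically deviate from the normative pattern
        symptoms = np.where(
            is_outlier,
            injected + 0.15 * eps,
            1.0 * np.abs(pc1) + 0.5 * eps,
        )

    truth = CohortTruth(
        schema_version=TRUTH_SCHEMA_VERSION,
        spec=dataclasses.asdict(spec),
        signal_locations=[int(j) for j in signal_locs],
        noise_sd=float(spec.noise_sd),
        total_sd=[float(s) for s in total_sd],
        outlier_subjects=[subject_ids[i] for i in out_idx],
        outlier_locations=outlier_locations,
        outlier_shifts=outlier_shifts,
        symptom_model=spec.symptom_model,
    )
    return Cohort(
        covariates=CovariateTable(X, subject_ids, covariate_names),
        responses=ResponseMatrix(Y, subject_ids, location_ids),
        group_ids=group_ids,
        symptoms=symptoms,
        truth=truth,
        surface=surface,
    )


def generate_prior_cohort(
    n_subjects: int,
    n_locations: int,
    length_scale: float = 0.3,
    signal_variance: float = 1.0,
    noise_sd: float = 1.0,
    n_covariates: int = 2,
    seed: int = 0,
) -> Cohort:
    """Simulate a cohort directly from the normative model's own prior.

    Each location's latent function is an independent draw from a GP with
    a squared-exponential ARD kernel on shared uniform covariates, plus
    Gaussian noise. The model class therefore matches the generator
    exactly, which is the reference condition for calibration checks of
    the cross-validated deviation Z-scores.
    """
    from .gp import Kernel, kernel_matrix

    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n_subjects, n_covariates))
    kern = Kernel(
        "se_ard", np.full(n_covariates, length_scale), signal_variance
    )
    K = kernel_matrix(kern, X, X) + 1e-10 * np.eye(n_subjects)
    F = np.linalg.cholesky(K) @ rng.normal(size=(n_subjects, n_locations))
    Y = F + rng.normal(0.0, noise_sd, size=(n_subjects, n_locations))
    subject_ids = [f"S{i:04d}" for i in range(n_subjects)]
    truth = CohortTruth(
        schema_version=TRUTH_SCHEMA_VERSION,
        spec={
            "kind": "prior",
            "length_scale": length_scale,
            "signal_variance": signal_variance,
            "noise_sd": noise_sd,
            "seed": seed,
        },
        signal_locations=list(range(n_locations)),
        noise_sd=float(noise_sd),
        total_sd=[float(np.sqrt(signal_variance + noise_sd**2))] * n_locations,
        outlier_subjects=[],
        outlier_locations={},
        outlier_shifts={},
        symptom_model="null",
    )
    return Cohort(
        covariates=CovariateTable(
            X, subject_ids, [f"x{j}" for j in range(n_covariates)]
        ),
        responses=ResponseMatrix(
            Y, subject_ids, [f"loc{j:05d}" for j in range(n_locations)]
        ),
        group_ids=list(subject_ids),
        symptoms=rng.normal(size=n_subjects),
        truth=truth,
        surface=F,
    )


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------


def write_fixture(cohort: Cohort, directory, nifti: bool = False) -> dict:
    """Write a cohort as the file set the CLI consumes.

    Emits covariates.tsv, responses.tsv, groups.tsv, symptoms.tsv and
    truth.json; with ``nifti=True`` additionally a 4D NIfTI image (one
    volume per subject) plus a 3D mask whose true voxels are the response
    locations. Returns the mapping of roles to paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    cov = pd.DataFrame(
        cohort.covariates.values,
        columns=cohort.covariates.covariate_names,
    )
    cov.insert(0, "subject_id", cohort.covariates.subject_ids)
    paths["covariates"] = directory / "covariates.tsv"
    cov.to_csv(paths["covariates"], sep="\t", index=False, float_format="%.17g")

    resp = pd.DataFrame(
        cohort.responses.values, columns=cohort.responses.location_ids
    )
    resp.insert(0, "subject_id", cohort.responses.subject_ids)
    paths["responses"] = directory / "responses.tsv"
    resp.to_csv(paths["responses"], sep="\t", index=False, float_format="%.17g")

    grp = pd.DataFrame(
        {"subject_id": cohort.covariates.subject_ids, "group_id": cohort.group_ids}
    )
    paths["groups"] = directory / "groups.tsv"
    grp.to_csv(paths["groups"], sep="\t", index=False)

    sym = pd.DataFrame(
        {"subject_id": cohort.covariates.subject_ids, "symptom": cohort.symptoms}
    )
    paths["symptoms"] = directory / "symptoms.tsv"
    sym.to_csv(paths["symptoms"], sep="\t", index=False, float_format="%.17g")

    paths["truth"] = directory / "truth.json"
    paths["truth"].write_text(cohort.truth.to_json())

    if nifti:
        from .io import write_responses_nifti

        paths["responses_nifti"], paths["mask"] = write_responses_nifti(
            cohort.responses, directory / "responses.nii", directory / "mask.nii"
        )
    return paths


def read_truth(path) -> CohortTruth:
    data = json.loads(Path(path).read_text())
    if data.get("schema_version") != TRUTH_SCHEMA_VERSION:
        raise ValidationError(
            f"truth schema version {data.get('schema_version')} unsupported"
        )
    return CohortTruth(**data)
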