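"""Shared fixtures: cross-validated pipeline runs reused across test modules.

The heavier cohort studies are session-scoped so each condition is fitted
once. Sizes are reduced relative to the package's reference desk-scale
conditions (see docs/methods.md) while keeping the features each check
depends on: enough training subjects for stable hyperparameters, and
enough locations for the 1% deviance tail to average several cells.
"""

import dataclasses

import numpy as np
import pytest

import normap as nm

GP_FAST = {"restarts": 1, "maxiter": 150}


@pytest.fixture(scope="session")
def prior_null_runs():
    """GP-prior cohorts (model class matches generator) under grouped CV:
    the reference condition for Z-score calibration. 6 seeds x 300 x 12."""
    runs = []
    for seed in range(6):
        cohort = nm.generate_prior_cohort(300, 12, seed=seed)
        _, _, npm, _ = nm.run_pipeline(
            cohort.covariates, cohort.responses, cohort.group_ids,
            k=4, seed=seed, gp_config=GP_FAST, final_fit=False,
        )
        runs.append((cohort, npm))
    return runs


@pytest.fixture(scope="session")
def null_cohort_runs():
    """Generator cohorts without planted outliers (symptoms at the extreme
    of the normal spectrum): null condition for outlier-rate calibration.
    4 seeds x 160 x 110."""
    runs = []
    for seed in range(4):
        spec = nm.CohortSpec(
            n_subjects=160, n_locations=110, outlier_fraction=0.0,
            outlier_n_locations=1, symptom_model="extreme-of-normal",
            seed=100 + seed,
        )
        cohort = nm.generate_cohort(spec)
        _, _, npm, _ = nm.run_pipeline(
            cohort.covariates, cohort.responses, cohort.group_ids,
            k=4, seed=seed, gp_config=GP_FAST, final_fit=False,
        )
        runs.append((cohort, npm))
    return runs


@pytest.fixture(scope="session")
def power_runs():
    """Cohorts with outliers planted at exactly +4 total-SD on 1% of
    locations (10 of 1000), for detection-power checks. 2 seeds x 120."""
    runs = []
    for seed in range(2):
        spec = nm.CohortSpec(
            n_subjects=120, n_locations=1000, outlier_fraction=0.05,
            outlier_n_locations=10, outlier_magnitude=4.0,
            outlier_magnitude_spread=0.0, outlier_sign="positive",
            symptom_model="null", seed=200 + seed,
        )
        cohort = nm.generate_cohort(spec)
        _, _, npm, _ = nm.run_pipeline(
            cohort.covariates, cohort.responses, cohort.group_ids,
            k=3, seed=seed, gp_config=GP_FAST, final_fit=False,
        )
        runs.append((cohort, npm))
    return runs


MIXTURE_SPEC = nm.CohortSpec(
    n_subjects=200, n_locations=100, outlier_fraction=0.05,
    outlier_n_locations=5, outlier_magnitude=4.0, outlier_sign="negative",
    symptom_model="mixture", seed=0,
)
#: top fractions chosen so the smallest subset keeps five subjects at the
#: reduced cohort size (the extreme-tail count of the reference analysis)
MIXTURE_FRACTIONS = (0.025, 0.05, 0.10, 0.15, 0.20)


@pytest.fixture(scope="session")
def mixture_runs():
    """Mixture-symptom cohorts: deviance-linked outliers coexist with
    extreme-of-normal subjects. 10 seeds x 200 x 100."""
    runs = []
    for seed in range(10):
        spec = dataclasses.replace(MIXTURE_SPEC, seed=300 + seed)
        cohort = nm.generate_cohort(spec)
        _, _, npm, _ = nm.run_pipeline(
            cohort.covariates, cohort.responses, cohort.group_ids,
            k=3, seed=seed, gp_config=GP_FAST, final_fit=False,
        )
        runs.append((cohort, npm))
    return runs


def outlier_mask(cohort) -> np.ndarray:
    return np.isin(
        cohort.covariates.subject_ids, cohort.truth.outlier_subjects
    )
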