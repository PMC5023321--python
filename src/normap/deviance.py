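"""Subject-level abnormality indices and inference on deviation maps.

A subject's normative probability map is a vector of per-location
Z-scores. Treating each subject as one block, the block-maxima device of
extreme value theory summarizes the subject by the extreme tail of that
vector — robustified here as a trimmed mean of the top tail (by default a
90%-trimmed mean of the top 1% of Z values). Across the cohort these
block summaries follow an extreme value distribution (GEV, with Gumbel as
the shape-zero special case), which converts a subject's summary deviance
into an upper-tail probability: a calibrated, cohort-referenced outlier
test.

Signed variants use the top 1% (positive), bottom 1% (negative, reported
with negative sign), or top 1% of absolute values; over- and
under-expression relative to the norm carry different information.

Spatial localization is separate: per subject, two-sided normal p-values
at each location are thresholded by Benjamini-Hochberg FDR, giving the
individualized map of deviating locations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gp import FitFailureError, ValidationError

log = logging.getLogger("normap")

MODES = ("positive", "negative", "absolute")


# ---------------------------------------------------------------------------
# Block-maxima deviance summaries
# ---------------------------------------------------------------------------


def _trimmed_tail_mean(values: np.ndarray, tail_fraction: float, trim_total: float) -> float:
    """Trimmed mean of the top ``tail_fraction`` block of ``values``.

    Tail size is ceil(tail_fraction * n); ``trim_total`` of the tail block
    is removed symmetrically (floor of half per side), always keeping at
    least one survivor.
    """
    n = values.size
    t = math.ceil(tail_fraction * n)
    tail = np.sort(values)[n - t:]
    per_side = math.floor(trim_total * t / 2.0)
    if t - 2 * per_side < 1:
        per_side = (t - 1) // 2
    kept = tail[per_side: t - per_side]
    return float(kept.mean())


def summarize_deviance(
    z: np.ndarray,
    mode: str = "absolute",
    tail_fraction: float = 0.01,
    trim_total: float = 0.90,
    subject_ids=None,
) -> np.ndarray:
    """Per-subject block-maxima deviance scores from an NPM Z matrix.

    mode ``"positive"`` summarizes the top tail of Z, ``"negative"`` the
    top tail of -Z (returned with negative sign), ``"absolute"`` the top
    tail of \\|Z\\|. NaN cells (flagged locations) are excluded per subject.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    if not 0 < tail_fraction <= 1:
        raise ValidationError("tail_fraction must lie in (0, 1]")
    if not 0 <= trim_total < 1:
        raise ValidationError("trim_total must lie in [0, 1)")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n_subj = z.shape[0]
    min_valid = math.ceil(1.0 / tail_fraction)
    out = np.empty(n_subj)
    for i in range(n_subj):
        row = z[i][np.isfinite(z[i])]
        if row.size == 0:
            sid = subject_ids[i] if subject_ids is not None else i
            raise ValidationError(f"subject {sid!r} has no valid Z values")
        if row.size < min_valid:
            sid = subject_ids[i] if subject_ids is not None else i
            raise ValidationError(
                f"subject {sid!r} has {row.size} valid locations; "
                f"tail fraction {tail_fraction} needs >= {min_valid}"
            )
        if mode == "positive":
            out[i] = _trimmed_tail_mean(row, tail_fraction, trim_total)
        elif mode == "negative":
            out[i] = -_trimmed_tail_mean(-row, tail_fraction, trim_total)
        else:
            out[i] = _trimmed_tail_mean(np.abs(row), tail_fraction, trim_total)
    return out


# ---------------------------------------------------------------------------
# Extreme value distribution fitting and p-values
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EVDFit:
    """Maximum-likelihood extreme value fit to cohort deviance scores.

    ``shape`` uses the GEV convention in which the Gumbel family is
    shape = 0 and heavy tails have shape > 0 (note scipy's ``genextreme``
    parameter ``c`` is the negative of this).
    """

    family: str
    location: float
    scale: float
    shape: float
    n_fit: int
    fit_log_likelihood: float

    def _frozen(self):
        if self.family == "gumbel":
            return stats.gumbel_r(loc=self.location, scale=self.scale)
        return stats.genextreme(-self.shape, loc=self.location, scale=self.scale)


def fit_evd(deviances, family: str = "gev") -> EVDFit:
    """Fit a Gumbel or generalized extreme value distribution by MLE.

    The fit is deterministic: scipy's moment-based initialization is
    used. GEV requires n >= 30 (below that Gumbel is enforced); a GEV fit
    that fails to produce a valid optimum falls back to Gumbel with a
    warning; a Gumbel failure is fatal.
    """
    d = np.asarray(deviances, dtype=float).ravel()
    if d.size < 2 or not np.all(np.isfinite(d)):
        raise ValidationError("need >= 2 finite deviance values")
    if family not in ("gev", "gumbel"):
        raise ValidationError("family must be 'gev' or 'gumbel'")
    if family == "gev" and d.size < 30:
        log.warning("n=%d < 30: enforcing gumbel instead of gev", d.size)
        family = "gumbel"

    if family == "gev":
        try:
            c, loc, scale = stats.genextreme.fit(d)
            ll = float(np.sum(stats.genextreme.logpdf(d, c, loc, scale)))
            if np.isfinite(ll) and scale > 0 and np.isfinite(c):
                return EVDFit("gev", float(loc), float(scale), float(-c),
                              int(d.size), ll)
        except Exception as e:  # scipy raises various failure types
            log.warning("GEV fit failed (%s); falling back to Gumbel", e)
        log.warning("GEV fit invalid; falling back to Gumbel")
        family = "gumbel"

    loc, scale = stats.gumbel_r.fit(d)
    ll = float(np.sum(stats.gumbel_r.logpdf(d, loc, scale)))
    if not (np.isfinite(ll) and scale > 0):
        raise FitFailureError("Gumbel MLE failed on deviance scores")
    return EVDFit("gumbel", float(loc), float(scale), 0.0, int(d.size), ll)


def evd_pvalue(fit: EVDFit, deviance) -> np.ndarray | float:
    """Upper-tail probability of a deviance score under the fitted EVD."""
    p = fit._frozen().sf(deviance)
    return float(p) if np.isscalar(deviance) else np.asarray(p)


@dataclass
class SubjectInference:
    """Cohort-referenced outlier calls per subject."""

    subject_ids: list[str]
    deviance: np.ndarray
    evd_p: np.ndarray
    is_outlier: np.ndarray
    alpha: float
    fit: EVDFit


def infer_subjects(
    deviances,
    subject_ids=None,
    family: str = "gev",
    alpha: float = 0.05,
    leave_one_out: bool = False,
) -> SubjectInference:
    """Fit the EVD to the cohort's deviance scores and test each subject.

    By default the fit includes the subject under test (cohort-level
    usage); ``leave_one_out=True`` refits without each subject for strict
    inference.
    """
    d = np.asarray(deviances, dtype=float).ravel()
    ids = (
        [str(s) for s in subject_ids]
        if subject_ids is not None
        else [str(i) for i in range(d.size)]
    )
    fit = fit_evd(d, family=family)
    if leave_one_out:
        p = np.empty(d.size)
        for i in range(d.size):
            f_i = fit_evd(np.delete(d, i), family=family)
            p[i] = evd_pvalue(f_i, d[i])
    else:
        p = np.asarray(evd_pvalue(fit, d))
    return SubjectInference(
        subject_ids=ids,
        deviance=d,
        evd_p=p,
        is_outlier=p < alpha,
        alpha=alpha,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# Per-subject FDR maps
# ---------------------------------------------------------------------------


def fdr_map(z_row, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided FDR-corrected deviation mask for one subject's Z row.

    Per-location two-sided normal p-values thresholded by the
    Benjamini-Hochberg step-up at level q. Returns (reject mask, adjusted
    p-values); NaN cells (flagged locations) are never rejected and get
    adjusted p = NaN.
    """
    z = np.asarray(z_row, dtype=float).ravel()
    if z.size == 0:
        raise ValidationError("empty Z row")
    valid = np.isfinite(z)
    mask = np.zeros(z.size, dtype=bool)
    p_adj = np.full(z.size, np.nan)
    if valid.any():
        p = 2.0 * stats.norm.sf(np.abs(z[valid]))
        rej, padj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
        mask[valid] = rej
        p_adj[valid] = padj
    return mask, p_adj


def count_deviating_subjects(z: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Per-location count of subjects whose FDR map rejects there.

    Convenience overlap summary for asking how individualized the
    deviation patterns are across the cohort.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    counts = np.zeros(z.shape[1], dtype=int)
    for i in range(z.shape[0]):
        mask, _ = fdr_map(z[i], q=q)
        counts += mask
    return counts


def n_deviant_locations(z: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Per-subject count of FDR-significant locations."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    return np.array([fdr_map(z[i], q=q)[0].sum() for i in range(z.shape[0])])


# ---------------------------------------------------------------------------
# Deviance-symptom tail correlations
# ---------------------------------------------------------------------------


def tail_correlation(
    deviance,
    symptoms,
    top_fractions=(0.01, 0.05, 0.10, 0.15, 0.20),
    mode: str = "negative",
) -> list[dict]:
    """Correlate deviance magnitude with a symptom in the most-deviant tail.

    Subjects are ranked by deviance magnitude (for the negative mode, by
    the negated — i.e. positive — negative deviance, so larger means more
    deviant) and a Pearson correlation between magnitude and symptom is
    computed within each top fraction. Returns one record per fraction
    with keys ``fraction, r, p, n``; a constant symptom vector within a
    subset yields r = NaN (undefined), never 0.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    d = np.asarray(deviance, dtype=float).ravel()
    s = np.asarray(symptoms, dtype=float).ravel()
    if d.shape != s.shape:
        raise ValidationError("deviance and symptom vectors are misaligned")
    magnitude = -d if mode == "negative" else d
    order = np.argsort(-magnitude, kind="stable")
    out = []
    for frac in top_fractions:
        n_top = math.ceil(frac * d.size)
        if n_top < 3:
            raise ValidationError(
                f"top fraction {frac} yields n={n_top} < 3 subjects"
            )
        idx = order[:n_top]
        ms, ss = magnitude[idx], s[idx]
        if np.ptp(ss) == 0 or np.ptp(ms) == 0:
            out.append({"fraction": frac, "r": float("nan"),
                        "p": float("nan"), "n": n_top})
            continue
        r, p = stats.pearsonr(ms, ss)
        out.append({"fraction": frac, "r": float(r), "p": float(p), "n": n_top})
    return out
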