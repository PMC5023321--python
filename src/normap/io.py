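"""File interfaces: tabular inputs, NIfTI responses, and model bundles.

Tabular inputs are TSV/CSV with a header row, one row per subject, and a
``subject_id`` column. Responses come either as a wide matrix file
(subjects x locations) or as a 4D NIfTI image (one volume per subject)
with a 3D mask selecting the in-analysis voxels; imaging inputs are
flattened to a ResponseMatrix with a recorded location-to-voxel table and
Z maps are written back in the same geometry.

A fitted normative model set is serialized to a versioned on-disk bundle
(NumPy archive of hyperparameters, normalization constants and training
data, plus a JSON manifest with the fold assignment and a config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import (
    CovariateTable,
    CVPredictions,
    FoldAssignment,
    NormativeModelSet,
    ResponseMatrix,
)
from .gp import SE_ARD, GPModel, Kernel, ValidationError

BUNDLE_VERSION = 1


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise ValidationError(f"{path} lacks a 'subject_id' column")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_covariates(path) -> CovariateTable:
    df = _read_table(path)
    names = [c for c in df.columns if c != "subject_id"]
    return CovariateTable(
        df[names].to_numpy(float), list(df["subject_id"]), names
    )


def read_responses_matrix(path) -> ResponseMatrix:
    df = _read_table(path)
    locs = [c for c in df.columns if c != "subject_id"]
    return ResponseMatrix(
        df[locs].to_numpy(float), list(df["subject_id"]), locs
    )


def read_groups(path) -> dict[str, str]:
    df = _read_table(path)
    col = "group_id" if "group_id" in df.columns else df.columns[1]
    return dict(zip(df["subject_id"], df[col].astype(str)))


def read_symptoms(path) -> dict[str, float]:
    df = _read_table(path)
    col = next(c for c in df.columns if c != "subject_id")
    return dict(zip(df["subject_id"], df[col].astype(float)))


# ---------------------------------------------------------------------------
# NIfTI responses
# ---------------------------------------------------------------------------


def write_responses_nifti(responses: ResponseMatrix, img_path, mask_path):
    """Pack a response matrix into a 4D NIfTI (subject axis last) + mask."""
    import nibabel as nib

    n, L = responses.values.shape
    # smallest near-cubic volume holding L voxels
    side = int(np.ceil(L ** (1 / 3)))
    shape = (side, side, max(1, int(np.ceil(L / side**2))))
    mask = np.zeros(shape, dtype=np.uint8)
    flat = np.unravel_index(np.arange(L), shape)
    mask[flat] = 1
    vol = np.zeros(shape + (n,), dtype=np.float64)
    vol[flat[0], flat[1], flat[2], :] = responses.values.T
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(vol, affine), str(img_path))
    nib.save(nib.Nifti1Image(mask, affine), str(mask_path))
    return Path(img_path), Path(mask_path)


def read_responses_nifti(img_path, mask_path, subject_ids=None) -> ResponseMatrix:
    """Flatten masked voxels of a 4D NIfTI to a ResponseMatrix.

    Location IDs record the voxel coordinates (``vox_i_j_k``) so maps can
    be written back into the input geometry.
    """
    import nibabel as nib

    img = nib.load(str(img_path))
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError("expected a 4D NIfTI (subjects along axis 3)")
    if data.shape[:3] != mask.shape:
        raise ValidationError("image and mask geometries differ")
    idx = np.argwhere(mask)
    vals = data[mask].T  # subjects x voxels
    loc_ids = [f"vox_{i}_{j}_{k}" for i, j, k in idx]
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(vals.shape[0])]
    return ResponseMatrix(vals, list(subject_ids), loc_ids)


def write_maps_nifti(values: np.ndarray, mask_path, out_path):
    """Write per-location values (subjects x locations) back into mask space."""
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    values = np.atleast_2d(values)
    if values.shape[1] != int(mask.sum()):
        raise ValidationError("value count does not match mask voxel count")
    vol = np.zeros(mask.shape + (values.shape[0],))
    vol[mask, :] = values.T
    nib.save(nib.Nifti1Image(vol, mask_img.affine), str(out_path))
    return Path(out_path)


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_bundle(
    directory,
    model_set: NormativeModelSet,
    folds: FoldAssignment,
    preds: CVPredictions | None = None,
    extra_config: dict | None = None,
):
    """Serialize a fitted model set (and optionally CV predictions)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    L = len(model_set.models)
    ok = [m for m in model_set.models if m is not None]
    if not ok:
        raise ValidationError("no successfully fitted locations to save")
    D = ok[0].kernel.n_covariates
    n = ok[0].train_inputs.shape[0]

    ls = np.full((L, D), np.nan)
    sv = np.full(L, np.nan)
    lv = np.full(L, np.nan)
    nv = np.full(L, np.nan)
    xm = np.full((L, D), np.nan)
    xs = np.full((L, D), np.nan)
    ym = np.full(L, np.nan)
    lml = np.full(L, np.nan)
    Xtr = np.full((L, n, D), np.nan)
    ytr = np.full((L, n), np.nan)
    variants = []
    for j, m in enumerate(model_set.models):
        if m is None:
            variants.append("")
            continue
        variants.append(m.kernel.variant)
        ls[j] = m.kernel.length_scales
        sv[j] = m.kernel.signal_variance
        lv[j] = m.kernel.linear_variance
        nv[j] = m.noise_variance
        xm[j] = m.x_mean
        xs[j] = m.x_sd
        ym[j] = m.y_mean
        lml[j] = m.log_marginal_likelihood
        Xtr[j] = m.train_inputs
        ytr[j] = m.train_targets

    np.savez_compressed(
        directory / "models.npz",
        length_scales=ls, signal_variance=sv, linear_variance=lv,
        noise_variance=nv, x_mean=xm, x_sd=xs, y_mean=ym,
        log_marginal_likelihood=lml, train_inputs=Xtr, train_targets=ytr,
        failed=model_set.failed, fold_index=folds.fold_index,
    )
    if preds is not None:
        np.savez_compressed(
            directory / "cv_predictions.npz",
            mean=preds.mean,
            function_variance=preds.function_variance,
            noise_variance=preds.noise_variance,
        )
    cfg = dict(model_set.config)
    cfg.update(extra_config or {})
    manifest = {
        "bundle_version": BUNDLE_VERSION,
        "n_locations": L,
        "location_ids": model_set.location_ids,
        "k_folds": folds.k,
        "group_ids": folds.group_ids,
        "kernel_variants": variants,
        "config": cfg,
        "config_hash": config_hash(cfg),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_bundle(directory) -> tuple[NormativeModelSet, FoldAssignment, CVPredictions | None]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest["bundle_version"] != BUNDLE_VERSION:
        raise ValidationError(
            f"unsupported bundle version {manifest['bundle_version']}"
        )
    arr = np.load(directory / "models.npz")
    L = manifest["n_locations"]
    models: list[GPModel | None] = []
    for j in range(L):
        variant = manifest["kernel_variants"][j]
        if not variant:
            models.append(None)
            continue
        kern = Kernel(
            variant=variant or SE_ARD,
            length_scales=arr["length_scales"][j],
            signal_variance=float(arr["signal_variance"][j]),
            linear_variance=float(arr["linear_variance"][j])
            if variant == "linear_se_ard" else 0.0,
        )
        models.append(
            GPModel(
                kernel=kern,
                noise_variance=float(arr["noise_variance"][j]),
                train_inputs=arr["train_inputs"][j],
                train_targets=arr["train_targets"][j],
                x_mean=arr["x_mean"][j],
                x_sd=arr["x_sd"][j],
                y_mean=float(arr["y_mean"][j]),
                log_marginal_likelihood=float(arr["log_marginal_likelihood"][j]),
            )
        )
    model_set = NormativeModelSet(
        models=models,
        location_ids=manifest["location_ids"],
        failed=arr["failed"],
        log_marginal_likelihoods=arr["log_marginal_likelihood"],
        config=manifest["config"],
    )
    folds = FoldAssignment(
        fold_index=arr["fold_index"],
        k=manifest["k_folds"],
        group_ids=manifest["group_ids"],
    )
    preds = None
    pred_path = directory / "cv_predictions.npz"
    if pred_path.exists():
        p = np.load(pred_path)
        preds = CVPredictions(
            mean=p["mean"],
            function_variance=p["function_variance"],
            noise_variance=p["noise_variance"],
        )
    return model_set, folds, preds
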