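"""The PolyVoxel Score estimator.

A mass-univariate z-map over voxels is thresholded at nominal significance
(P < 0.01), the correlation matrix R of the retained training columns is
regularized by keeping its r largest eigenvalues and flooring the rest at
the r-th largest, and posterior weights are the decorrelated statistics

    w_r = R_r^{-1} z .

A subject's PVS is the linear score w_r^T x over retained voxels.  The rank
r is selected by stratified k-fold cross-validation over a grid, maximizing
held-out AUC; the selected value is the rounded mean of per-fold optima (so
it may fall off-grid, e.g. r = 13 from a grid without 13).

Models are oriented so that a *higher* PVS means "more archetype-like"
(mean training case score above mean control score); fitted weights are
negated if needed to enforce this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datatypes import (
    AlignmentError,
    EmptyModelError,
    InputError,
    MatrixContractError,
    VoxelImageSet,
)
from .preprocess import TransformSpec, apply_spec, fit_transform

__all__ = [
    "UnivariateStats",
    "PVSModel",
    "CVResult",
    "DEFAULT_R_GRID",
    "univariate_z",
    "threshold_voxels",
    "regularized_inverse",
    "fit_weights",
    "score",
    "crossval_select_r",
    "fit_pvs",
]

#: Regularization-rank grid; the sentinel "M" means "no regularization"
#: (rank equal to the number of retained voxels).
DEFAULT_R_GRID = (1, 5, 10, 20, 50, 100, 200, 500, 1000, "M")

FORMAT_VERSION = "polyvoxel-model-1"

_MIN_P = 1e-300  # two-sided p floor before the normal-quantile map


@dataclass
class UnivariateStats:
    """Per-voxel association of intensity with case status."""

    z: np.ndarray
    p: np.ndarray
    retained: np.ndarray  # bool per voxel


@dataclass
class CVResult:
    """Cross-validated rank selection record."""

    grid: tuple
    fold_grids: list  # resolved numeric grid per fold ("M" -> retained count)
    auc: np.ndarray  # (k, len(grid)) held-out AUC
    fold_optima: np.ndarray  # (k,) fold-optimal resolved r
    selected_r: int
    seed: int
    metric: str = "auc"


@dataclass
class PVSModel:
    """Fitted archetype scorer."""

    retained_idx: np.ndarray  # 0-based indices into the mask voxel order
    z: np.ndarray  # univariate z over retained voxels
    r: int
    weights: np.ndarray  # posterior weights w_r over retained voxels
    spec: TransformSpec
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """Single-file model archive (NumPy .npz with a JSON header)."""
        np.savez_compressed(
            path,
            format_version=np.array(FORMAT_VERSION),
            retained_idx=self.retained_idx,
            z=self.z,
            r=np.array(self.r),
            weights=self.weights,
            spec_train_sorted=self.spec.train_sorted,
            spec_train_mapped=self.spec.train_mapped,
            spec_coef=self.spec.coef,
            meta=np.array(json.dumps(
                {
                    **self.meta,
                    "design_columns": self.spec.design_columns,
                    "scanner_levels": self.spec.scanner_levels,
                    "blom_offset": self.spec.blom_offset,
                }
            )),
        )

    @classmethod
    def load(cls, path) -> "PVSModel":
        with np.load(path, allow_pickle=False) as f:
            if str(f["format_version"]) != FORMAT_VERSION:
                raise InputError(f"unknown model format {f['format_version']}")
            meta = json.loads(str(f["meta"]))
            spec = TransformSpec(
                train_sorted=f["spec_train_sorted"],
                train_mapped=f["spec_train_mapped"],
                coef=f["spec_coef"],
                design_columns=meta.pop("design_columns"),
                scanner_levels=meta.pop("scanner_levels"),
                blom_offset=meta.pop("blom_offset"),
            )
            return cls(
                retained_idx=f["retained_idx"],
                z=f["z"],
                r=int(f["r"]),
                weights=f["weights"],
                spec=spec,
                meta=meta,
            )

    def weight_map(self, mask: np.ndarray) -> np.ndarray:
        """Weights scattered back into the mask volume (NaN off-model)."""
        vol = np.full(mask.shape, np.nan)
        flat_idx = np.flatnonzero(mask.ravel(order="C"))[self.retained_idx]
        vol.ravel(order="C")[flat_idx] = self.weights
        return vol


def univariate_z(X: np.ndarray, y: np.ndarray) -> UnivariateStats:
    """Per-voxel z-statistic of the simple-regression slope of column on y.

    Computed as the Pearson-correlation t-statistic mapped to a standard
    normal deviate through its two-sided p-value.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise InputError("X rows and y length differ")
    classes = np.unique(y)
    if len(classes) < 2:
        raise InputError("y contains a single class")
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    xnorm = np.sqrt((Xc**2).sum(axis=0))
    xnorm[xnorm == 0] = np.inf  # constant column -> r = 0
    r = (Xc.T @ yc) / (xnorm * np.sqrt((yc**2).sum()))
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), _MIN_P)
    z = np.sign(t) * stats.norm.isf(p / 2.0)
    return UnivariateStats(z=z, p=p, retained=np.zeros(X.shape[1], dtype=bool))


def threshold_voxels(ustats: UnivariateStats, p_thresh: float = 0.01) -> np.ndarray:
    """Retain voxels with two-sided p < p_thresh (|z| above the normal
    quantile).  Raises if nothing survives."""
    retained = ustats.p < p_thresh
    if not retained.any():
        raise EmptyModelError(
            f"no voxel significant at P < {p_thresh} "
            f"(min p = {ustats.p.min():.3g})"
        )
    ustats.retained = retained
    return retained


def regularized_inverse(R: np.ndarray, r: int) -> np.ndarray:
    """Inverse of the eigenvalue-regularized correlation matrix.

    With R = U S U^T (eigenvalues descending, tiny negatives clamped to 0),
    S_r keeps the r largest eigenvalues and replaces the rest with the r-th
    largest; returns U S_r^{-1} U^T.  An exactly-zero floor (possible when
    r exceeds the sample rank) is raised to max_eig * 1e-12 so the inverse
    stays defined.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise MatrixContractError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise MatrixContractError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise MatrixContractError("R must have unit diagonal")
    if r < 1:
        raise InputError(f"rank r must be >= 1, got {r}")
    m = R.shape[0]
    r = min(int(r), m)
    evals, evecs = np.linalg.eigh(R)
    evals = evals[::-1].copy()
    evecs = evecs[:, ::-1]
    np.clip(evals, 0.0, None, out=evals)
    floor = evals[r - 1]
    if floor <= 0.0:
        floor = max(evals[0], 1.0) * 1e-12
    s_r = np.concatenate([np.maximum(evals[:r], floor), np.full(m - r, floor)])
    inv = (evecs / s_r) @ evecs.T
    return (inv + inv.T) / 2.0


def fit_weights(z: np.ndarray, R: np.ndarray, r: int) -> np.ndarray:
    """Posterior (decorrelated) weights w_r = R_r^{-1} z."""
    z = np.asarray(z, dtype=float)
    if len(z) != R.shape[0]:
        raise InputError("z length and R dimension differ")
    return regularized_inverse(R, r) @ z


def score(X: np.ndarray, model: PVSModel) -> np.ndarray:
    """PVS per subject: w_r^T x over retained voxels.

    ``X`` is the full-width *preprocessed* matrix (apply the model's
    TransformSpec first, or use :func:`score_images`).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] <= int(model.retained_idx.max()):
        raise AlignmentError(
            f"matrix has {X.shape[1]} voxels; model expects indices up to "
            f"{int(model.retained_idx.max())}"
        )
    return X[:, model.retained_idx] @ model.weights


def score_images(model: PVSModel, images: VoxelImageSet, table: pd.DataFrame) -> np.ndarray:
    """Preprocess raw masked intensities with the model's frozen spec and
    score.  Rows of ``table`` must align with image rows."""
    if images.n_voxels != model.spec.n_voxels:
        raise AlignmentError(
            f"image set has {images.n_voxels} voxels, model spec "
            f"expects {model.spec.n_voxels}"
        )
    X = apply_spec(images.data, table, model.spec)
    return score(X, model)


def _fit_on_matrix(X_pre: np.ndarray, y: np.ndarray, r: int, p_thresh: float):
    """z -> threshold -> R over retained columns -> weights. Internal."""
    ustats = univariate_z(X_pre, y)
    retained = threshold_voxels(ustats, p_thresh)
    idx = np.flatnonzero(retained)
    Xr = X_pre[:, idx]
    R = np.corrcoef(Xr, rowvar=False)
    if R.ndim == 0:  # single retained voxel
        R = np.ones((1, 1))
    w = fit_weights(ustats.z[idx], R, r)
    return ustats, idx, R, w


def crossval_select_r(
    X_raw: np.ndarray,
    table: pd.DataFrame,
    y: np.ndarray,
    grid=DEFAULT_R_GRID,
    k: int = 5,
    seed: int = 0,
    p_thresh: float = 0.01,
) -> CVResult:
    """Stratified k-fold selection of the regularization rank.

    Preprocessing, the z-map, the threshold, R and the weights are fitted on
    the training folds only; held-out AUC is computed per grid value.  Ties
    break to the smallest r (strongest regularization); the selected r is
    the rounded mean of the fold optima and may lie off-grid.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise InputError("y contains a single class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = np.zeros((k, len(grid)))
    fold_grids, fold_optima = [], []
    for fold, (tr, te) in enumerate(skf.split(X_raw, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise InputError(f"fold {fold} has a single class")
        X_tr, spec = fit_transform(X_raw[tr], table.iloc[tr])
        X_te = apply_spec(X_raw[te], table.iloc[te], spec)
        ustats = univariate_z(X_tr, y[tr])
        retained = threshold_voxels(ustats, p_thresh)
        idx = np.flatnonzero(retained)
        R = np.corrcoef(X_tr[:, idx], rowvar=False)
        if R.ndim == 0:
            R = np.ones((1, 1))
        resolved = [len(idx) if g == "M" else min(int(g), len(idx)) for g in grid]
        fold_grids.append(resolved)
        for j, r_val in enumerate(resolved):
            w = fit_weights(ustats.z[idx], R, r_val)
            scores = X_te[:, idx] @ w
            aucs[fold, j] = roc_auc_score(y[te], scores)
        # smallest r wins on exact AUC ties (strongest regularization)
        best_auc = aucs[fold].max()
        ties = [resolved[j] for j in range(len(grid)) if aucs[fold, j] == best_auc]
        fold_optima.append(min(ties))
    fold_optima = np.asarray(fold_optima)
    selected = max(1, int(round(fold_optima.mean())))
    return CVResult(
        grid=tuple(grid),
        fold_grids=fold_grids,
        auc=aucs,
        fold_optima=fold_optima,
        selected_r=selected,
        seed=seed,
    )


def fit_pvs(
    images: VoxelImageSet,
    table: pd.DataFrame,
    y: np.ndarray,
    r: int,
    p_thresh: float = 0.01,
    seed: int = 0,
) -> PVSModel:
    """Fit the full PVS model on a (matched) training set.

    Runs preprocess -> univariate z -> threshold -> correlation of retained
    columns -> w_r = R_r^{-1} z, then orients the model so the mean training
    case score exceeds the mean control score.
    """
    y = np.asarray(y, dtype=int)
    if len(table) != images.n_subjects or len(y) != images.n_subjects:
        raise InputError("images, table and y must align")
    X_pre, spec = fit_transform(images.data, table)
    ustats, idx, R, w = _fit_on_matrix(X_pre, y, r, p_thresh)
    oriented = False
    train_scores = X_pre[:, idx] @ w
    if train_scores[y == 1].mean() < train_scores[y == 0].mean():
        w = -w
        oriented = True
    return PVSModel(
        retained_idx=idx,
        z=ustats.z[idx],
        r=int(r),
        weights=w,
        spec=spec,
        meta={
            "n_train": int(images.n_subjects),
            "n_cases": int(y.sum()),
            "p_thresh": float(p_thresh),
            "seed": int(seed),
            "negated_for_orientation": bool(oriented),
            "n_retained": int(len(idx)),
        },
    )
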