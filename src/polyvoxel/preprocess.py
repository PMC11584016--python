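"""Voxel-matrix preprocessing: rank-based inverse-normal transform and
covariate residualization.

Each voxel column is quantile-transformed to a normal distribution (Blom
offset: Phi^-1((rank - 3/8) / (n + 1/4)), average ranks for ties) and then
replaced by its least-squares residual on a covariate design of intercept,
age, sex, scanner (one-hot, reference dropped) and 10 genetic PCs.  The
training-fitted state (per-voxel rank maps and residualization coefficients)
is frozen in a :class:`TransformSpec` and applied unchanged to test data,
with clamped extrapolation beyond the training range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AlignmentError,
    DegenerateColumnError,
    DesignError,
    InputError,
    PC_COLUMNS,
)

__all__ = [
    "rank_inverse_normal",
    "build_design",
    "residualize",
    "fit_transform",
    "apply_spec",
    "TransformSpec",
]

BLOM_OFFSET = 0.375


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Map values to standard-normal quantiles through their ranks.

    Uses Phi^-1((rank - 3/8) / (n + 1/4)) with average ranks for ties, so the
    output is strictly monotone in the input ranks and has mean ~ 0.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InputError("rank_inverse_normal expects a 1-D vector")
    n = len(x)
    if n < 3:
        raise InputError(f"need at least 3 values, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateColumnError("constant input cannot be rank-transformed")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - BLOM_OFFSET) / (n + 1 - 2 * BLOM_OFFSET))


def _rint_columns(matrix: np.ndarray) -> np.ndarray:
    """Column-wise rank-inverse-normal transform (vectorized)."""
    n = matrix.shape[0]
    if n < 3:
        raise InputError("need at least 3 subjects")
    if (np.ptp(matrix, axis=0) == 0).any():
        bad = np.flatnonzero(np.ptp(matrix, axis=0) == 0)[:5]
        raise DegenerateColumnError(f"constant voxel columns: {bad}")
    ranks = stats.rankdata(matrix, method="average", axis=0)
    return stats.norm.ppf((ranks - BLOM_OFFSET) / (n + 1 - 2 * BLOM_OFFSET))


def build_design(table: pd.DataFrame, scanner_levels=None, check_rank=True):
    """Covariate design matrix: intercept, age, sex(M=1), scanner one-hot
    (first level dropped), PC1..PC10.

    Returns ``(design, column_names, scanner_levels)``.  Passing the training
    ``scanner_levels`` reproduces the training parameterization on test data.
    ``check_rank=False`` skips the full-rank check (appropriate when only
    *applying* frozen coefficients, where no estimation happens).
    """
    if scanner_levels is None:
        scanner_levels = sorted(table["scanner"].unique())
    else:
        unknown = set(table["scanner"]) - set(scanner_levels)
        if unknown:
            raise DesignError(f"scanner levels unseen in training: {sorted(unknown)}")
    cols = [np.ones(len(table)), table["age"].to_numpy(float),
            (table["sex"] == "M").to_numpy(float)]
    names = ["intercept", "age", "sex_M"]
    for level in scanner_levels[1:]:
        cols.append((table["scanner"] == level).to_numpy(float))
        names.append(f"scanner_{level}")
    for pc in PC_COLUMNS:
        cols.append(table[pc].to_numpy(float))
        names.append(pc)
    design = np.column_stack(cols)
    if not check_rank:
        return design, names, list(scanner_levels)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name a minimal set of columns involved in the collinearity
        keep, collinear = [], []
        for j in range(design.shape[1]):
            trial = design[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                collinear.append(names[j])
        raise DesignError(f"design is rank deficient; collinear columns: {collinear}")
    return design, names, list(scanner_levels)


def residualize(matrix: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residual of each column on the design."""
    matrix = np.asarray(matrix, dtype=float)
    design = np.asarray(design, dtype=float)
    if matrix.shape[0] != design.shape[0]:
        raise InputError(
            f"matrix has {matrix.shape[0]} rows, design {design.shape[0]}"
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DesignError("design is rank deficient")
    beta, *_ = np.linalg.lstsq(design, matrix, rcond=None)
    return matrix - design @ beta


@dataclass
class TransformSpec:
    """Frozen training-time preprocessing state.

    ``train_sorted`` / ``train_mapped`` hold, per voxel, the sorted training
    values and their inverse-normal images; out-of-sample values are mapped
    by linear interpolation between these nodes and *clamped* to the boundary
    quantiles beyond the training range.  ``coef`` holds the per-voxel
    residualization coefficients on the training design.
    """

    train_sorted: np.ndarray  # (n_train, n_voxels)
    train_mapped: np.ndarray  # (n_train, n_voxels)
    coef: np.ndarray  # (n_design_cols, n_voxels)
    design_columns: list
    scanner_levels: list
    blom_offset: float = BLOM_OFFSET

    @property
    def n_voxels(self) -> int:
        return self.train_sorted.shape[1]


def fit_transform(matrix: np.ndarray, table: pd.DataFrame):
    """Fit the transform-then-residualize preprocessing on training data.

    Returns ``(preprocessed_matrix, spec)``.  Residuals are orthogonal to
    every design column.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != len(table):
        raise InputError("matrix rows and subject table length differ")
    transformed = _rint_columns(matrix)
    design, names, scanner_levels = build_design(table)
    beta, *_ = np.linalg.lstsq(design, transformed, rcond=None)
    resid = transformed - design @ beta

    order = np.argsort(matrix, axis=0, kind="stable")
    train_sorted = np.take_along_axis(matrix, order, axis=0)
    train_mapped = np.take_along_axis(transformed, order, axis=0)
    spec = TransformSpec(
        train_sorted=train_sorted,
        train_mapped=train_mapped,
        coef=beta,
        design_columns=names,
        scanner_levels=scanner_levels,
    )
    return resid, spec


def apply_spec(matrix: np.ndarray, table: pd.DataFrame, spec: TransformSpec) -> np.ndarray:
    """Apply frozen preprocessing to new data (no statistics re-estimated).

    Values beyond the training range map to the boundary quantile (clamp);
    residualization uses the training coefficients with the new subjects'
    covariates.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != spec.n_voxels:
        raise AlignmentError(
            f"matrix has {matrix.shape[1]} voxels, spec expects {spec.n_voxels}"
        )
    if matrix.shape[0] != len(table):
        raise InputError("matrix rows and subject table length differ")
    transformed = np.empty_like(matrix)
    for j in range(spec.n_voxels):
        transformed[:, j] = np.interp(
            matrix[:, j], spec.train_sorted[:, j], spec.train_mapped[:, j]
        )
    design, _, _ = build_design(
        table, scanner_levels=spec.scanner_levels, check_rank=False
    )
    if design.shape[1] != spec.coef.shape[0]:
        raise DesignError("test design incompatible with training coefficients")
    return transformed - design @ spec.coef
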