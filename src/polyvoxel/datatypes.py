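"""Shared containers and exceptions for the PVS pipeline.

The cohort backbone is a plain :class:`pandas.DataFrame` ("subject table")
with a documented column contract rather than a bespoke class; helpers here
validate that contract.  Voxel data lives in :class:`VoxelImageSet`, a thin
subjects-by-masked-voxels matrix that remembers the mask geometry so weight
maps can be exported back to NIfTI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPE_CLASSES = ("wildtype", "heterozygote", "homozygote")

#: Columns every subject table must carry (diagnosis flags are ``dx_*``).
SUBJECT_COLUMNS = (
    "subject_id",
    "genotype_class",
    "age",
    "sex",
    "scanner",
    *[f"pc{i}" for i in range(1, 11)],
    "has_imaging",
)

PC_COLUMNS = tuple(f"pc{i}" for i in range(1, 11))


class PolyvoxelError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PolyvoxelError):
    """Invalid generator or run configuration."""


class InputError(PolyvoxelError):
    """Inconsistent or malformed inputs (length / label problems)."""


class AlignmentError(PolyvoxelError):
    """Voxel or subject alignment mismatch between artifacts."""


class DesignError(PolyvoxelError):
    """Rank-deficient or otherwise unusable design matrix."""


class DegenerateColumnError(PolyvoxelError):
    """A voxel column is constant and cannot be rank-transformed."""


class MatchingError(PolyvoxelError):
    """Not enough eligible controls inside an exact matching stratum."""


class EmptyModelError(PolyvoxelError):
    """No voxel survived the significance threshold."""


class MatrixContractError(PolyvoxelError):
    """Correlation-matrix input violates symmetry / unit-diagonal contract."""


class SeparationError(PolyvoxelError):
    """Weighted logistic fit failed to converge (e.g. perfect separation)."""


class CategoryError(PolyvoxelError):
    """A categorical risk-model level is empty."""


class SelectionError(PolyvoxelError):
    """Empty variant selection for replication analysis."""


@dataclass
class VoxelImageSet:
    """Subjects × masked-voxels matrix with mask geometry.

    Parameters
    ----------
    data:
        ``(n_subjects, n_voxels)`` float array.  Voxel order is the C-order
        scan of ``mask`` (``mask_volume[mask_volume > 0]`` order) — fixed and
        relied on by every downstream stage.
    subject_ids:
        Length ``n_subjects`` identifiers aligned to ``data`` rows.
    modality:
        ``"T2w"`` (intensities; the classifier input) or ``"T2star"``
        (T2* relaxation times stored in **milliseconds**).
    mask:
        3-D boolean array; ``mask.sum() == n_voxels``.
    affine:
        4×4 voxel-to-world affine, retained for NIfTI export.
    """

    data: np.ndarray
    subject_ids: np.ndarray
    modality: str
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise InputError("image data must be 2-D (subjects x voxels)")
        if len(self.subject_ids) != self.data.shape[0]:
            raise InputError(
                f"{len(self.subject_ids)} subject ids for "
                f"{self.data.shape[0]} data rows"
            )
        if int(self.mask.sum()) != self.data.shape[1]:
            raise AlignmentError(
                f"mask has {int(self.mask.sum())} voxels but data has "
                f"{self.data.shape[1]} columns"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def select_subjects(self, subject_ids) -> "VoxelImageSet":
        """Row-subset (and reorder) by subject id."""
        index = pd.Index(self.subject_ids)
        locs = index.get_indexer(np.asarray(subject_ids))
        if (locs < 0).any():
            missing = np.asarray(subject_ids)[locs < 0][:5]
            raise AlignmentError(f"subjects missing from image set: {missing}")
        return VoxelImageSet(
            data=self.data[locs],
            subject_ids=self.subject_ids[locs],
            modality=self.modality,
            mask=self.mask,
            affine=self.affine,
        )


@dataclass
class AtlasLabels:
    """Integer region labels over the masked voxels (0 = unlabeled)."""

    labels: np.ndarray  # (n_voxels,) int, mask scan order
    names: dict  # region id -> region name (id 0 optional)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise InputError("atlas labels must be 1-D over masked voxels")
        if (self.labels < 0).any():
            raise InputError("atlas region ids must be nonnegative")
        missing = set(np.unique(self.labels)) - set(self.names) - {0}
        if missing:
            raise InputError(f"atlas ids without names: {sorted(missing)}")

    def region_ids(self) -> np.ndarray:
        return np.unique(self.labels)


def validate_subject_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the subject-table column contract; returns the table."""
    missing = [c for c in SUBJECT_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"subject table missing columns: {missing}")
    if table["subject_id"].duplicated().any():
        raise InputError("subject_id values must be unique")
    bad = set(table["genotype_class"].unique()) - set(GENOTYPE_CLASSES)
    if bad:
        raise InputError(f"unknown genotype classes: {sorted(bad)}")
    return table


def outcome_columns(table: pd.DataFrame) -> list:
    """Diagnosis-flag columns (``dx_`` prefix)."""
    return [c for c in table.columns if c.startswith("dx_")]


def subsample_c_mask(table: pd.DataFrame) -> pd.Series:
    """Membership in subsample C = subsample B ∪ all homozygotes.

    C is a superset of B so it cannot live in the disjoint ``subsample``
    label column; it is derived on demand.
    """
    if "subsample" not in table.columns:
        raise InputError("table has no 'subsample' column; run split_samples")
    return (table["subsample"] == "B") | (table["genotype_class"] == "homozygote")
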