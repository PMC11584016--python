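"""Iron-concentration estimation from T2*-derived relaxation rates.

R2* = 1/T2* is approximately linear in tissue iron concentration; the
conversion to micrograms of iron per gram of dry tissue uses the published
liver-calibrated relationship

    iron [ug/g dry] = C * R2* [Hz] / 3.2,   C = 2000/36 .

T2* values are stored in **milliseconds** throughout this package, so the
rate conversion uses the factor 1000 (R2* [Hz] = 1000 / T2* [ms]).  The
calibration's caveats (two-echo estimation, liver-tissue constants) are
documented limitations, not modelled.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import EmptyModelError, InputError, VoxelImageSet

__all__ = [
    "IRON_C",
    "r2star_from_t2star",
    "mean_r2star",
    "iron_concentration",
    "group_iron_means",
    "iron_table",
]

IRON_C = 2000.0 / 36.0  # calibration constant, ug/g dry per (Hz / 3.2)


def r2star_from_t2star(t2star_ms):
    """R2* [Hz] = 1000 / T2* [ms]."""
    t = np.asarray(t2star_ms, dtype=float)
    if (t <= 0).any():
        raise InputError("T2* must be positive")
    return 1000.0 / t


def mean_r2star(images: VoxelImageSet, retained_idx: np.ndarray) -> np.ndarray:
    """Per-subject arithmetic mean R2* [Hz] over the retained voxels.

    ``retained_idx`` normally comes from the fitted PVS model (the P < 0.01
    voxel set).
    """
    retained_idx = np.asarray(retained_idx)
    if retained_idx.size == 0:
        raise EmptyModelError("empty retained-voxel set")
    if images.modality != "T2star":
        raise InputError(f"expected a T2star image set, got {images.modality}")
    rates = r2star_from_t2star(images.data[:, retained_idx])
    return rates.mean(axis=1)


def iron_concentration(r2star_hz):
    """ug iron / g dry tissue = (2000/36) * R2* / 3.2 (exact)."""
    r = np.asarray(r2star_hz, dtype=float)
    if (r < 0).any():
        raise InputError("R2* must be nonnegative")
    out = IRON_C * r / 3.2
    return float(out) if out.ndim == 0 else out


def iron_table(
    images: VoxelImageSet, retained_idx: np.ndarray
) -> pd.DataFrame:
    """Per-subject iron estimates: subject_id, mean_r2star_hz, iron_ug_per_g_dry."""
    rates = mean_r2star(images, retained_idx)
    return pd.DataFrame(
        {
            "subject_id": images.subject_ids,
            "mean_r2star_hz": rates,
            "iron_ug_per_g_dry": iron_concentration(rates),
        }
    )


def group_iron_means(estimates: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-group mean iron concentration with standard error.

    ``groups`` is a categorical aligned to ``estimates`` rows.  Empty groups
    (categories with no members) are skipped with a warning.
    """
    if len(groups) != len(estimates):
        raise InputError("groups and estimates differ in length")
    if isinstance(groups, pd.Categorical) or isinstance(
        getattr(groups, "dtype", None), pd.CategoricalDtype
    ):
        levels = list(pd.Series(groups).cat.categories)
        groups = pd.Series(np.asarray(groups), index=estimates.index)
    else:
        groups = pd.Series(np.asarray(groups), index=estimates.index)
        levels = list(pd.unique(groups))
    rows = []
    for g in levels:
        vals = estimates.loc[groups == g, "iron_ug_per_g_dry"].to_numpy()
        if len(vals) == 0:
            warnings.warn(f"group {g!r} is empty; skipped")
            continue
        se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        rows.append((g, float(vals.mean()), float(se), len(vals)))
    return pd.DataFrame(rows, columns=["group", "mean_iron", "se", "n"])
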