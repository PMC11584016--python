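"""Region-level feature importance and region-wise R2*-PVS correlations.

A weight map (univariate z or posterior w_r, over retained voxels) is scaled
to unit Euclidean length; a region's importance is the sum of squares of the
normalized entries over its voxels.  Unlabeled voxels (atlas id 0) go into
an explicit "unlabeled" bucket so the fractions conserve to 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AtlasLabels, InputError, VoxelImageSet

__all__ = ["region_importance", "region_pvs_correlation", "importance_table"]

UNLABELED = 0


def region_importance(weight_map: np.ndarray, atlas: AtlasLabels) -> pd.DataFrame:
    """Fraction of squared unit-normalized map weight per region.

    ``weight_map`` and ``atlas.labels`` are aligned (same voxel subset and
    order).  Returns a DataFrame with columns region_id, region_name,
    importance; fractions (including the unlabeled bucket) sum to 1.
    """
    w = np.asarray(weight_map, dtype=float)
    if w.ndim != 1:
        raise InputError("weight map must be 1-D")
    if len(w) != len(atlas.labels):
        raise InputError(
            f"map has {len(w)} voxels, atlas {len(atlas.labels)}"
        )
    norm = np.linalg.norm(w)
    if norm == 0:
        raise InputError("all-zero weight map cannot be normalized")
    sq = (w / norm) ** 2
    rows = []
    for rid in atlas.region_ids():
        name = "unlabeled" if rid == UNLABELED else atlas.names[rid]
        rows.append((int(rid), name, float(sq[atlas.labels == rid].sum())))
    return pd.DataFrame(rows, columns=["region_id", "region_name", "importance"])


def region_pvs_correlation(
    r2star: VoxelImageSet, atlas: AtlasLabels, pvs: np.ndarray
) -> pd.DataFrame:
    """Pearson correlation of per-region mean R2* with the PVS.

    ``r2star`` holds T2* times in ms over the same voxel subset/order as the
    atlas; R2* = 1000/T2* is averaged over each region's voxels per subject.
    Regions with zero voxels are skipped with a warning.
    """
    pvs = np.asarray(pvs, dtype=float)
    if len(pvs) != r2star.n_subjects:
        raise InputError("PVS length and image subjects differ")
    if len(atlas.labels) != r2star.n_voxels:
        raise InputError("atlas and image voxel counts differ")
    rates = 1000.0 / r2star.data  # ms -> Hz
    rows = []
    for rid in atlas.region_ids():
        if rid == UNLABELED:
            continue
        sel = atlas.labels == rid
        if not sel.any():  # pragma: no cover - region_ids comes from labels
            warnings.warn(f"region {rid} has no voxels; skipped")
            continue
        mean_rate = rates[:, sel].mean(axis=1)
        r, p = stats.pearsonr(mean_rate, pvs)
        rows.append((int(rid), atlas.names[rid], float(r), float(p)))
    return pd.DataFrame(rows, columns=["region_id", "region_name", "pvs_r2star_corr", "p"])


def importance_table(
    z_map: np.ndarray,
    w_map: np.ndarray,
    atlas: AtlasLabels,
    r2star: VoxelImageSet | None = None,
    pvs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Combined per-region summary: univariate and posterior importance,
    optionally with the R2*-PVS correlation column."""
    uni = region_importance(z_map, atlas).rename(
        columns={"importance": "importance_univariate"}
    )
    post = region_importance(w_map, atlas).rename(
        columns={"importance": "importance_posterior"}
    )
    out = uni.merge(post, on=["region_id", "region_name"])
    if r2star is not None and pvs is not None:
        corr = region_pvs_correlation(r2star, atlas, pvs)
        out = out.merge(
            corr[["region_id", "pvs_r2star_corr"]], on="region_id", how="left"
        )
    return out
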