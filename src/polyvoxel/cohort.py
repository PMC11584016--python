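"""Matched case-control construction and subsample splitting.

The training subsample (A) consists of every archetype homozygote with
imaging plus covariate-matched wildtype controls at a fixed ratio (default
4 controls per case).  Heterozygotes are excluded from both sides.  Matching
is exact on sex and scanner and greedy nearest-neighbour on standardized
(age, PC1..PC10) Euclidean distance, without replacement, in a seeded random
case order.  The scoring subsample (B) is every imaged subject outside A who
is not homozygous; subsample C adds back *all* homozygotes (imaging not
required) for the quantile risk analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    InputError,
    MatchingError,
    PC_COLUMNS,
    validate_subject_table,
)

__all__ = ["match_controls", "split_samples"]

_DISTANCE_COLS = ("age",) + PC_COLUMNS


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (values - values.mean(axis=0)) / sd


def match_controls(
    subjects: pd.DataFrame, ratio: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Select all eligible cases plus ``ratio`` matched controls per case.

    Cases are homozygotes with imaging; control candidates are imaged
    wildtypes (heterozygotes excluded entirely).  Raises
    :class:`MatchingError` naming the (sex, scanner) stratum if any case
    cannot receive its full complement of controls.

    Returns the matched sub-table with a ``matched_case_id`` column on
    controls (NA for cases).
    """
    validate_subject_table(subjects)
    if ratio < 1:
        raise InputError(f"ratio must be a positive integer, got {ratio}")

    imaged = subjects[subjects["has_imaging"] == 1]
    cases = imaged[imaged["genotype_class"] == "homozygote"]
    pool = imaged[imaged["genotype_class"] == "wildtype"]
    if cases.empty:
        raise MatchingError("no homozygote cases with imaging")

    # standardize distance covariates over the eligible set jointly
    eligible = pd.concat([cases, pool])
    z = pd.DataFrame(
        _standardize(eligible[list(_DISTANCE_COLS)].to_numpy(float)),
        index=eligible.index,
    )

    rng = np.random.default_rng(seed)
    case_order = cases.index.to_numpy()[rng.permutation(len(cases))]

    used: set = set()
    matched_rows = []
    for case_idx in case_order:
        sex = subjects.at[case_idx, "sex"]
        scanner = subjects.at[case_idx, "scanner"]
        stratum = pool[(pool["sex"] == sex) & (pool["scanner"] == scanner)]
        stratum = stratum[~stratum.index.isin(used)]
        if len(stratum) < ratio:
            raise MatchingError(
                f"stratum (sex={sex}, scanner={scanner}) has "
                f"{len(stratum)} unused controls; {ratio} needed "
                f"for case {subjects.at[case_idx, 'subject_id']}"
            )
        diffs = z.loc[stratum.index].to_numpy() - z.loc[case_idx].to_numpy()
        dist = np.sqrt((diffs**2).sum(axis=1))
        order = np.argsort(dist, kind="stable")[:ratio]
        chosen = stratum.index.to_numpy()[order]
        used.update(chosen)
        matched_rows.append((case_idx, chosen))

    case_ids = subjects.loc[[c for c, _ in matched_rows], "subject_id"]
    out_cases = subjects.loc[[c for c, _ in matched_rows]].copy()
    out_cases["matched_case_id"] = pd.NA

    ctrl_idx = np.concatenate([ch for _, ch in matched_rows])
    out_ctrls = subjects.loc[ctrl_idx].copy()
    out_ctrls["matched_case_id"] = np.repeat(case_ids.to_numpy(), ratio)

    out = pd.concat([out_cases, out_ctrls]).sort_index()
    return out


def split_samples(
    subjects: pd.DataFrame, matched: pd.DataFrame
) -> pd.DataFrame:
    """Label subsamples: A = matched training set; B = imaged, non-A,
    non-homozygote; everything else 'none'.

    Subsample C (= B plus all homozygotes) is derived downstream via
    :func:`polyvoxel.datatypes.subsample_c_mask`.  Raises on A/B overlap.
    """
    validate_subject_table(subjects)
    out = subjects.copy()
    a_ids = set(matched["subject_id"])
    missing = a_ids - set(out["subject_id"])
    if missing:
        raise InputError(f"matched subjects absent from table: {sorted(missing)[:5]}")

    in_a = out["subject_id"].isin(a_ids)
    in_b = (
        (out["has_imaging"] == 1)
        & ~in_a
        & (out["genotype_class"] != "homozygote")
    )
    if (in_a & in_b).any():
        raise InputError("subsamples A and B overlap")  # pragma: no cover
    out["subsample"] = np.select([in_a, in_b], ["A", "B"], default="none")
    return out
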