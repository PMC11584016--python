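"""Inverse-probability-weighted logistic risk models.

Cases of a disorder are depleted in imaging subsamples relative to the full
cohort; regressions therefore weight each imaged case by the prevalence
ratio (full / imaging) and every other observation by 1, recovering
estimates closer to population prevalence.  Two analyses are provided:

* ``weighted_logistic`` — continuous PVS (standardized, so the OR is per SD)
  against a binary outcome, with covariates;
* ``quantile_risk`` — four PVS quartiles (boundaries estimated among
  non-homozygous imaged subjects, ties to the lower quartile) plus a
  homozygote category, with the 4th quartile as the reference level; this is
  the U-shape analysis.

Wald (model-based) confidence intervals come from the weighted information
matrix by default; a sandwich (robust) option is available, as IPW analyses
often warrant it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import (
    CategoryError,
    DesignError,
    InputError,
    SeparationError,
)
from .preprocess import build_design

__all__ = ["WeightScheme", "RiskFit", "estimate_ipw", "weighted_logistic", "quantile_risk"]

QUARTILE_LEVELS = ("Q1", "Q2", "Q3", "Q4", "homozygote")
REFERENCE_LEVEL = "Q4"


@dataclass
class WeightScheme:
    """Case weight for one outcome; controls always weigh 1."""

    case_weight: float
    outcome: str
    control_weight: float = 1.0

    def weights_for(self, outcome_flag: np.ndarray, has_imaging=None) -> np.ndarray:
        """Per-observation weights.  When ``has_imaging`` is given, the case
        weight applies only to imaged cases (non-imaged observations carry
        weight 1, as they are not depleted)."""
        flag = np.asarray(outcome_flag, dtype=bool)
        w = np.where(flag, self.case_weight, self.control_weight)
        if has_imaging is not None:
            w = np.where(np.asarray(has_imaging, dtype=bool), w, 1.0)
        return w.astype(float)


@dataclass
class RiskFit:
    """Weighted logistic regression result."""

    table: pd.DataFrame  # term, coef, or_, ci_low, ci_high, z, p
    n_cases: int
    n_controls: int
    weight_scheme: str
    meta: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        row = self.table[self.table["term"] == name]
        if row.empty:
            raise KeyError(f"no term {name!r} in fit")
        return row.iloc[0]


def estimate_ipw(
    full: pd.DataFrame, imaging: pd.DataFrame, outcome: str
) -> WeightScheme:
    """Case weight = full-sample prevalence / imaging-subsample prevalence."""
    for name, tbl in (("full", full), ("imaging", imaging)):
        if outcome not in tbl.columns:
            raise InputError(f"outcome {outcome!r} missing from {name} table")
    prev_full = full[outcome].mean()
    prev_img = imaging[outcome].mean()
    if prev_img == 0:
        raise InputError(f"no imaging cases of {outcome!r}; IPW undefined")
    return WeightScheme(case_weight=float(prev_full / prev_img), outcome=outcome)


def _wald_table(result, names) -> pd.DataFrame:
    coefs = result.params
    ses = result.bse
    z = coefs / ses
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": names,
            "coef": coefs,
            "or_": np.exp(coefs),
            "ci_low": np.exp(coefs - 1.959963984540054 * ses),
            "ci_high": np.exp(coefs + 1.959963984540054 * ses),
            "z": z,
            "p": p,
        }
    )


def _fit_weighted_glm(y, design, names, weights, robust):
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DesignError("risk-model design is rank deficient")
    model = sm.GLM(y, design, family=sm.families.Binomial(), freq_weights=weights)
    try:
        result = model.fit(cov_type="HC0" if robust else "nonrobust", maxiter=200)
    except Exception as exc:  # statsmodels raises various linalg errors
        raise SeparationError(f"weighted logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(result.params)) or not np.all(np.isfinite(result.bse)):
        raise SeparationError("non-finite estimates; possible separation")
    if np.abs(result.params).max() > 30:
        raise SeparationError("diverging coefficients; possible separation")
    return _wald_table(result, names)


def weighted_logistic(
    table: pd.DataFrame,
    outcome: str,
    pvs: np.ndarray,
    weights: np.ndarray | WeightScheme | None = None,
    covariates: bool = True,
    robust: bool = False,
) -> RiskFit:
    """Weighted logistic regression of a binary outcome on the PVS.

    The PVS is standardized to unit variance before entry, so the reported
    OR is per SD of PVS.  ``weights`` may be a per-observation vector, a
    :class:`WeightScheme`, or None (unweighted).
    """
    y = table[outcome].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise InputError(f"outcome {outcome!r} has a single class")
    pvs = np.asarray(pvs, dtype=float)
    if len(pvs) != len(table):
        raise InputError("PVS length and table rows differ")
    if isinstance(weights, WeightScheme):
        w = weights.weights_for(y, table.get("has_imaging"))
        scheme = f"ipw case_weight={weights.case_weight:.4f}"
    elif weights is None:
        w = np.ones(len(y))
        scheme = "unweighted"
    else:
        w = np.asarray(weights, dtype=float)
        scheme = "custom"

    pvs_std = (pvs - pvs.mean()) / pvs.std(ddof=0)
    if covariates:
        design, names, _ = build_design(table)
        design = np.column_stack([design, pvs_std])
        names = names + ["pvs"]
    else:
        design = np.column_stack([np.ones(len(y)), pvs_std])
        names = ["intercept", "pvs"]

    fit_table = _fit_weighted_glm(y, design, names, w, robust)
    return RiskFit(
        table=fit_table,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        weight_scheme=scheme,
        meta={"pvs_scale": "per-SD", "robust": robust, "outcome": outcome},
    )


def assign_quartiles(pvs: np.ndarray, homozygote: np.ndarray) -> np.ndarray:
    """Quartile labels from sample quartiles of PVS among non-homozygotes.

    Boundary ties go to the lower quartile; homozygotes get their own
    category and are excluded from boundary estimation.
    """
    pvs = np.asarray(pvs, dtype=float)
    hom = np.asarray(homozygote, dtype=bool)
    if hom.all():
        raise InputError("no non-homozygous subjects to define quartiles")
    bounds = np.quantile(pvs[~hom], [0.25, 0.5, 0.75])
    q = np.searchsorted(bounds, pvs, side="left")  # == boundary -> lower
    labels = np.array([f"Q{i + 1}" for i in q], dtype=object)
    labels[hom] = "homozygote"
    return labels


def quantile_risk(
    table: pd.DataFrame,
    pvs: np.ndarray,
    homozygote: np.ndarray,
    outcome: str,
    weights: np.ndarray | WeightScheme | None = None,
    covariates: bool = True,
    robust: bool = False,
) -> RiskFit:
    """Per-group ORs (PVS quartiles + homozygotes) against quartile 4.

    The reference level Q4 never appears in the output table; every OR is
    interpretable against it.
    """
    y = table[outcome].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise InputError(f"outcome {outcome!r} has a single class")
    labels = assign_quartiles(pvs, homozygote)
    counts = pd.Series(labels).value_counts()
    for level in QUARTILE_LEVELS:
        if counts.get(level, 0) == 0:
            raise CategoryError(f"risk category {level!r} is empty")

    if isinstance(weights, WeightScheme):
        w = weights.weights_for(y, table.get("has_imaging"))
        scheme = f"ipw case_weight={weights.case_weight:.4f}"
    elif weights is None:
        w = np.ones(len(y))
        scheme = "unweighted"
    else:
        w = np.asarray(weights, dtype=float)
        scheme = "custom"

    group_cols, group_names = [], []
    for level in QUARTILE_LEVELS:
        if level == REFERENCE_LEVEL:
            continue
        group_cols.append((labels == level).astype(float))
        group_names.append(level)

    if covariates:
        design, names, _ = build_design(table)
    else:
        design, names = np.ones((len(y), 1)), ["intercept"]
    design = np.column_stack([design] + group_cols)
    names = list(names) + group_names

    fit_table = _fit_weighted_glm(y, design, names, w, robust)
    return RiskFit(
        table=fit_table,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        weight_scheme=scheme,
        meta={
            "reference": REFERENCE_LEVEL,
            "robust": robust,
            "outcome": outcome,
            "group_sizes": {k: int(v) for k, v in counts.items()},
        },
    )
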