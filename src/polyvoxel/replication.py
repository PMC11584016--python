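"""Discovery/replication analytics for score-associated variants.

Mass-univariate association of the PVS with variant dosages (per-variant OLS
with shared covariates), effect-size correlation between cohorts, and exact
two-sided binomial sign concordance.  Two-sided binomial p-values use the
tail-doubling rule, p = min(1, 2 * min(P(X <= k), P(X >= k))) at null
probability 1/2; zero effect estimates count as discordant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DegenerateColumnError,
    InputError,
    SelectionError,
)

__all__ = [
    "mass_univariate_assoc",
    "sign_concordance",
    "effect_correlation",
    "ConcordanceResult",
    "binomial_two_sided",
]


@dataclass
class ConcordanceResult:
    n_selected: int
    n_concordant: int
    proportion: float
    p_value: float
    beta_correlation: float


def binomial_two_sided(k: int, n: int) -> float:
    """Exact two-sided binomial p at null probability 1/2, by doubling the
    smaller tail and capping at 1."""
    if not 0 <= k <= n:
        raise InputError(f"need 0 <= k <= n, got k={k}, n={n}")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def mass_univariate_assoc(
    genotypes: pd.DataFrame | np.ndarray,
    pvs: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant OLS of PVS on dosage plus covariates.

    ``genotypes`` is subjects × variants with dosages in [0, 2] (a DataFrame
    supplies variant ids via columns).  Monomorphic variants are flagged
    (``tested = False``) rather than tested.  Returns an association table
    with columns variant, beta, se, z, p, tested.
    """
    if isinstance(genotypes, pd.DataFrame):
        variant_ids = list(genotypes.columns)
        G = genotypes.to_numpy(float)
    else:
        G = np.asarray(genotypes, dtype=float)
        variant_ids = [f"v{j}" for j in range(G.shape[1])]
    pvs = np.asarray(pvs, dtype=float)
    n = len(pvs)
    if G.shape[0] != n:
        raise InputError("genotype rows and PVS length differ")
    if (G < 0).any() or (G > 2).any():
        raise InputError("dosages must lie in [0, 2]")
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.shape[0] != n:
            raise InputError("covariate rows and PVS length differ")
        has_const = any(np.ptp(C[:, j]) == 0 for j in range(C.shape[1]))
        if not has_const:  # ensure an intercept column is present
            C = np.column_stack([np.ones(n), C])

    rows = []
    for j, vid in enumerate(variant_ids):
        g = G[:, j]
        if np.ptp(g) == 0:
            rows.append((vid, np.nan, np.nan, np.nan, np.nan, False))
            continue
        X = np.column_stack([C, g])
        beta_all, _, rank, _ = np.linalg.lstsq(X, pvs, rcond=None)
        resid = pvs - X @ beta_all
        df = n - X.shape[1]
        if df <= 0 or rank < X.shape[1]:
            rows.append((vid, np.nan, np.nan, np.nan, np.nan, False))
            continue
        sigma2 = resid @ resid / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        beta = float(beta_all[-1])
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append((vid, beta, se, t, p, True))
    return pd.DataFrame(
        rows, columns=["variant", "beta", "se", "z", "p", "tested"]
    )


def _aligned_betas(discovery, replication, selection):
    selection = list(selection)
    if not selection:
        raise SelectionError("empty variant selection")
    d = discovery.set_index("variant")
    r = replication.set_index("variant")
    missing = [v for v in selection if v not in d.index or v not in r.index]
    if missing:
        raise InputError(f"variants missing from a cohort: {missing[:5]}")
    return (
        d.loc[selection, "beta"].to_numpy(float),
        r.loc[selection, "beta"].to_numpy(float),
    )


def sign_concordance(
    discovery: pd.DataFrame, replication: pd.DataFrame, selection
) -> ConcordanceResult:
    """Direction agreement of selected variants' effects across cohorts.

    Concordant means strictly equal nonzero signs (a zero beta counts as
    discordant).  The p-value is the exact two-sided binomial test at null
    probability 1/2; the Pearson correlation of betas is reported alongside.
    """
    bd, br = _aligned_betas(discovery, replication, selection)
    concordant = (np.sign(bd) == np.sign(br)) & (np.sign(bd) != 0)
    k, n = int(concordant.sum()), len(concordant)
    if n >= 3 and np.ptp(bd) > 0 and np.ptp(br) > 0:
        r = float(stats.pearsonr(bd, br).statistic)
    else:
        r = np.nan
    return ConcordanceResult(
        n_selected=n,
        n_concordant=k,
        proportion=k / n,
        p_value=binomial_two_sided(k, n),
        beta_correlation=r,
    )


def effect_correlation(
    discovery: pd.DataFrame, replication: pd.DataFrame, selection
):
    """Pearson correlation of selected betas across cohorts, with its
    two-sided p-value.  Returns ``(r, p)``."""
    bd, br = _aligned_betas(discovery, replication, selection)
    if len(bd) < 3:
        raise InputError("need at least 3 selected variants")
    if np.ptp(bd) == 0 or np.ptp(br) == 0:
        raise DegenerateColumnError("constant betas; correlation undefined")
    res = stats.pearsonr(bd, br)
    return float(res.statistic), float(res.pvalue)
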