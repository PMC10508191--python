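"""Discovery-to-replication consistency of inversion effects.

Two statistics over (inversion, phenotype) pairs that are nominally
significant in the discovery cohort: the correlation of effect estimates
between cohorts — raw, and disattenuated for estimation error by a
method-of-moments correction that subtracts the mean squared standard
error from each cohort's beta variance — and the rate of effect-sign
agreement with an exact binomial test against chance (0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneralizationResult",
    "select_pairs",
    "beta_correlation",
    "sign_concordance",
    "generalize",
    "paired_frame_columns",
]


def paired_frame_columns(bd, br, se_d=0.0, se_r=0.0) -> pd.DataFrame:
    """Assemble a paired effect table from arrays (helper for studies)."""
    k = len(bd)
    return pd.DataFrame(
        {
            "beta_d": np.asarray(bd, float),
            "se_d": np.broadcast_to(np.asarray(se_d, float), k).copy(),
            "p_d": 0.0,
            "beta_r": np.asarray(br, float),
            "se_r": np.broadcast_to(np.asarray(se_r, float), k).copy(),
            "p_r": 1.0,
        }
    )


@dataclass
class GeneralizationResult:
    phenotype_class: str
    n_pairs: int
    r_raw: float
    r_adjusted: float  # NaN when the corrected variance is non-positive
    r_p: float
    concordance: float
    binom_p: float
    adjusted_defined: bool = True


def select_pairs(
    discovery: pd.DataFrame, replication: pd.DataFrame, p_cut: float = 0.05
) -> pd.DataFrame:
    """Join discovery-significant pairs to replication estimates.

    Both frames need columns (inversion_id, phenotype_id, beta, se, p);
    selection uses the discovery p only.  Returns a frame with columns
    beta_d, se_d, p_d, beta_r, se_r, p_r keyed by (inversion, phenotype).
    """
    keys = ["inversion_id", "phenotype_id"]
    d = discovery[discovery["p"] < p_cut]
    if d.empty:
        raise ValueError(f"no discovery pairs below p = {p_cut}")
    merged = d.merge(replication, on=keys, suffixes=("_d", "_r"))
    if merged.empty:
        raise ValueError("no overlapping (inversion, phenotype) pairs")
    return merged[keys + ["beta_d", "se_d", "p_d", "beta_r", "se_r", "p_r"]]


def beta_correlation(pairs: pd.DataFrame) -> tuple[float, float, float]:
    """Correlation of effect estimates, raw and error-disattenuated.

    r_raw is the Pearson correlation of (beta_d, beta_r) with a two-sided
    t-test p.  Sampling noise in each beta attenuates r_raw, so the
    adjusted estimate divides the between-cohort covariance by the
    geometric mean of the error-corrected variances,

        r_adj = cov(b_d, b_r) / sqrt[(var(b_d) - mean(se_d^2)) *
                                     (var(b_r) - mean(se_r^2))],

    clamped to [-1, 1]; it is NaN when either corrected variance is
    non-positive.

    Returns (r_raw, r_adjusted, r_p).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    bd = pairs["beta_d"].to_numpy(dtype=float)
    br = pairs["beta_r"].to_numpy(dtype=float)
    r_raw, r_p = stats.pearsonr(bd, br)
    cov = np.cov(bd, br)[0, 1]
    vd = np.var(bd, ddof=1) - np.mean(pairs["se_d"].to_numpy(dtype=float) ** 2)
    vr = np.var(br, ddof=1) - np.mean(pairs["se_r"].to_numpy(dtype=float) ** 2)
    if vd <= 0 or vr <= 0:
        r_adj = float("nan")
    else:
        r_adj = float(np.clip(cov / np.sqrt(vd * vr), -1.0, 1.0))
    return float(r_raw), r_adj, float(r_p)


def sign_concordance(
    pairs: pd.DataFrame, alternative: str = "greater"
) -> tuple[float, float]:
    """Sign agreement of effects with an exact binomial test.

    concordance = k/n where k counts pairs with sign(beta_d) =
    sign(beta_r); an exact zero beta counts as discordant
    (conservative).  binom_p tests k successes in n trials against 0.5,
    one-sided (greater) by default.
    """
    if len(pairs) < 1:
        raise ValueError("need at least 1 pair")
    bd = pairs["beta_d"].to_numpy(dtype=float)
    br = pairs["beta_r"].to_numpy(dtype=float)
    agree = (np.sign(bd) == np.sign(br)) & (bd != 0) & (br != 0)
    k, n = int(agree.sum()), len(pairs)
    binom_p = stats.binomtest(k, n, 0.5, alternative=alternative).pvalue
    return k / n, float(binom_p)


def generalize(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    phenotype_class: str = "all",
    p_cut: float = 0.05,
) -> GeneralizationResult:
    """Full generalization analysis for one phenotype class."""
    pairs = select_pairs(discovery, replication, p_cut=p_cut)
    r_raw, r_adj, r_p = beta_correlation(pairs)
    conc, binom_p = sign_concordance(pairs)
    return GeneralizationResult(
        phenotype_class=phenotype_class,
        n_pairs=len(pairs),
        r_raw=r_raw,
        r_adjusted=r_adj,
        r_p=r_p,
        concordance=conc,
        binom_p=binom_p,
        adjusted_defined=not np.isnan(r_adj),
    )
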