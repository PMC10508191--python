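"""Inversion-phenotype association with the study's statistical pipeline.

The procedure: genotype and sample QC, relatedness pruning on a genetic
relationship matrix (GRM), covariate (and optionally global-measure)
residualization of each phenotype, a rank-based inverse normal
transformation (INT) of the residuals, a joint additive multiple
regression of each transformed phenotype on all inversion dosages,
eigenvalue-based effective-test multiplicity correction, and a
stepwise SNP-conditional refit to ask whether an inversion signal is
tagged by region SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable",
    "AssociationResult",
    "MultiplicityResult",
    "QCReport",
    "snp_sample_qc",
    "compute_grm",
    "relatedness_filter",
    "preresidualize",
    "rank_int",
    "dc_coding",
    "joint_inversion_regression",
    "effective_tests",
    "significance_tiers",
    "conditional_adjustment",
]


@dataclass
class PhenotypeTable:
    """Samples x phenotypes with covariates and global measures.

    covariates must include age, sex (0/1), site (categorical), quality
    proxy; global_map sends each phenotype column to the column of
    global_measures regressed out when adjust_global is requested (e.g.
    a regional surface area to total surface area).
    """

    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    global_measures: pd.DataFrame
    global_map: dict

    def __post_init__(self) -> None:
        if not self.phenotypes.index.equals(self.covariates.index):
            raise ValueError("covariates must be aligned to phenotype sample ids")
        stds = self.phenotypes.std(axis=0)
        const = stds[stds == 0].index.tolist()
        if const:
            raise ValueError(f"constant phenotype column(s): {const}")

    @property
    def sample_ids(self) -> list:
        return list(self.phenotypes.index)


@dataclass
class AssociationResult:
    inversion_id: str
    phenotype_id: str
    beta: float
    se: float
    t: float
    p: float
    incremental_r2: float
    n: int
    coding: str = "autosomal"
    tier: str = "none"


@dataclass
class MultiplicityResult:
    """Effective number of independent phenotypes and Bonferroni level."""

    t_e: float
    eigenvalues: np.ndarray
    alpha: float = 0.05

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.t_e


@dataclass
class QCReport:
    n_individuals_removed: int
    n_snps_missingness: int
    n_snps_hwe: int
    n_snps_maf: int
    retained_individuals: np.ndarray = field(default_factory=lambda: np.array([]))
    retained_snps: np.ndarray = field(default_factory=lambda: np.array([]))


def _hwe_chi2_p(geno: np.ndarray) -> float:
    """HWE goodness-of-fit p (1 df) from a genotype vector with NaN missing."""
    g = geno[~np.isnan(geno)]
    n = len(g)
    if n == 0:
        return 1.0
    counts = np.array([(g == s).sum() for s in (0, 1, 2)], dtype=float)
    q = (counts[1] + 2 * counts[2]) / (2 * n)
    p = 1 - q
    if q in (0.0, 1.0):
        return 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    chi2 = ((counts - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=1))


def snp_sample_qc(
    genotypes: np.ndarray,
    max_ind_missing: float = 0.10,
    max_snp_missing: float = 0.05,
    hwe_p: float = 1e-6,
    min_maf: float = 0.01,
) -> tuple[np.ndarray, QCReport]:
    """Standard genotype QC: individuals first, then SNPs.

    Drops individuals with more than 10% missing SNPs, then SNPs with
    more than 5% missingness, failing HWE at p < 1e-6, or with minor
    allele frequency below 0.01 (criteria applied in that order; a SNP
    is counted against the first criterion it fails).

    genotypes is (n, m) with np.nan for missing.
    """
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    ind_missing = np.isnan(G).mean(axis=1)
    keep_ind = ind_missing <= max_ind_missing
    G2 = G[keep_ind]

    snp_missing = np.isnan(G2).mean(axis=0)
    fail_missing = snp_missing > max_snp_missing
    hwe = np.array([_hwe_chi2_p(G2[:, j]) for j in range(m)])
    fail_hwe = (hwe < hwe_p) & ~fail_missing
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(G2, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    fail_maf = (maf < min_maf) & ~fail_missing & ~fail_hwe

    keep_snp = ~(fail_missing | fail_hwe | fail_maf)
    if not keep_snp.any():
        raise ValueError("all SNPs removed by QC")
    report = QCReport(
        n_individuals_removed=int((~keep_ind).sum()),
        n_snps_missingness=int(fail_missing.sum()),
        n_snps_hwe=int(fail_hwe.sum()),
        n_snps_maf=int(fail_maf.sum()),
        retained_individuals=np.where(keep_ind)[0],
        retained_snps=np.where(keep_snp)[0],
    )
    return G2[:, keep_snp], report


def compute_grm(dosages: np.ndarray, allele_freqs: np.ndarray | None = None) -> np.ndarray:
    """Genetic relationship matrix from autosomal dosages.

    A_jk = (1/M) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    over the M polymorphic SNPs.
    """
    X = np.asarray(dosages, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("GRM needs at least 2 individuals")
    p = X.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, float)
    usable = (p > 0) & (p < 1)
    if not usable.any():
        raise ValueError("no polymorphic SNPs for GRM")
    Xc = X[:, usable] - 2 * p[usable]
    Z = Xc / np.sqrt(2 * p[usable] * (1 - p[usable]))
    return (Z @ Z.T) / usable.sum()


def relatedness_filter(grm: np.ndarray, threshold: float = 0.1) -> tuple[list, list]:
    """Greedy pruning of related pairs (off-diagonal GRM > threshold).

    While any pair exceeds the threshold, remove the individual in the
    most such pairs (ties broken toward the larger index).  Returns
    (retained indices, removal log).
    """
    A = np.asarray(grm, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("GRM must be square and symmetric")
    n = A.shape[0]
    over = (A > threshold) & ~np.eye(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    removed = []
    while True:
        deg = (over & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        worst = np.where(deg == deg.max())[0][-1]  # tie -> larger index
        active[worst] = False
        removed.append(int(worst))
    return list(np.where(active)[0]), removed


def _design_matrix(covariates: pd.DataFrame, extra: np.ndarray | None = None) -> np.ndarray:
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    for c in covariates.columns:
        v = covariates[c]
        if c == "site" or v.dtype == object or str(v.dtype) == "category":
            dummies = pd.get_dummies(v, prefix=c, drop_first=True, dtype=float)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy())
                names.append(dc)
        else:
            arr = v.to_numpy(dtype=float)
            if np.std(arr) > 0:
                cols.append(arr)
                names.append(c)
    X = np.column_stack(cols)
    if extra is not None:
        X = np.column_stack([X, extra])
        names.append("global")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a collinear column for the error message
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                bad.append(names[j])
        raise ValueError(f"rank-deficient covariate design; collinear column(s): {bad}")
    return X


def preresidualize(pheno: PhenotypeTable, adjust_global: bool = False) -> pd.DataFrame:
    """OLS residuals of each phenotype on the covariates.

    With adjust_global, each phenotype's mapped global measure joins the
    design (total area for regional areas, etc.), so residuals express
    regional effects beyond global size.
    """
    out = {}
    for col in pheno.phenotypes.columns:
        extra = None
        if adjust_global:
            gcol = pheno.global_map.get(col)
            if gcol is not None:
                extra = pheno.global_measures[gcol].to_numpy(dtype=float)
        X = _design_matrix(pheno.covariates, extra)
        y = pheno.phenotypes[col].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[col] = y - X @ coef
    return pd.DataFrame(out, index=pheno.phenotypes.index)


def rank_int(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transformation (Blom offset).

    v -> Phi^{-1}((rank(v) - c) / (n + 1 - 2c)) with c = 3/8 and average
    ranks for ties; the output preserves the input's weak ordering and
    has a standard-normal marginal.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("rank_int requires n >= 3")
    if np.ptp(v) == 0:
        raise ValueError("all values identical; no ordering information")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))


def dc_coding(genotypes: np.ndarray, sex: np.ndarray, mode: str = "full_dc") -> np.ndarray:
    """X-linked dosage coding.

    Input male values are hemizygous allele counts in {0, 1}; females
    are diploid {0, 1, 2}.  Under full dosage compensation males are
    coded {0, 2} (one active X in females balances the male dose);
    under no DC they stay {0, 1}.
    """
    g = np.asarray(genotypes, dtype=float)
    sex = np.asarray(sex)
    male = sex == 1
    if not np.isin(g[male], (0, 1)).all():
        raise ValueError("male X genotypes must be hemizygous {0, 1}")
    if mode == "full_dc":
        out = g.copy()
        out[male] = 2 * out[male]
        return out
    if mode == "no_dc":
        return g.copy()
    raise ValueError(f"unknown DC mode {mode!r}")


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS fit returning (beta, se, t, p, rss, df_resid)."""
    n, k = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, rss, df


def joint_inversion_regression(
    pheno: pd.DataFrame,
    dosages: pd.DataFrame,
    coding: str = "autosomal",
) -> list:
    """Joint additive regression of each phenotype on all inversions.

    One OLS fit per phenotype with every inversion dosage as a
    simultaneous predictor plus an intercept.  incremental_r2 is
    R^2(full) - R^2(full minus that inversion) — the variance uniquely
    explained by that inversion.
    """
    ids = list(dosages.columns)
    D = dosages.to_numpy(dtype=float)
    n, m = D.shape
    if n <= m + 1:
        raise ValueError("need n > number of inversions + 1")
    corr = np.corrcoef(D, rowvar=False)
    if m > 1:
        iu = np.triu_indices(m, 1)
        j = np.argmax(np.abs(corr[iu]))
        if np.abs(corr[iu][j]) > 1 - 1e-10:
            raise ValueError(
                f"collinear dosage columns: {ids[iu[0][j]]} and {ids[iu[1][j]]}"
            )
    X = np.column_stack([np.ones(n), D])
    results = []
    for col in pheno.columns:
        y = pheno[col].to_numpy(dtype=float)
        tss = float(((y - y.mean()) ** 2).sum())
        beta, se, t, p, rss, df = _ols(X, y)
        r2_full = 1 - rss / tss
        for j, inv_id in enumerate(ids):
            X_red = np.delete(X, j + 1, axis=1)
            _, _, _, _, rss_red, _ = _ols(X_red, y)
            r2_red = 1 - rss_red / tss
            results.append(
                AssociationResult(
                    inversion_id=inv_id,
                    phenotype_id=col,
                    beta=float(beta[j + 1]),
                    se=float(se[j + 1]),
                    t=float(t[j + 1]),
                    p=float(p[j + 1]),
                    incremental_r2=max(float(r2_full - r2_red), 0.0),
                    n=n,
                    coding=coding,
                )
            )
    return results


def effective_tests(
    corr: np.ndarray, alpha: float = 0.05, method: str = "li_ji"
) -> MultiplicityResult:
    """Effective number of independent phenotypes from the spectrum.

    Li-Ji (default): t_e = sum_i [ 1(lambda_i >= 1) + (lambda_i -
    floor(lambda_i)) ].  Nyholt: t_e = 1 + (M - 1)(1 - var(lambda)/M).
    The Bonferroni level is alpha / t_e.
    """
    C = np.asarray(corr, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be square symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(C)[::-1]
    if lam.min() < -1e-8:
        raise ValueError("correlation matrix is not PSD within tolerance")
    lam = np.clip(lam, 0.0, None)
    M = len(lam)
    if method == "li_ji":
        # snap near-integer eigenvalues so floor() is stable to rounding
        near = np.round(lam)
        lam_s = np.where(np.abs(lam - near) < 1e-9, near, lam)
        t_e = float(((lam_s >= 1).astype(float) + (lam_s - np.floor(lam_s))).sum())
    elif method == "nyholt":
        t_e = float(1 + (M - 1) * (1 - np.var(lam, ddof=1) / M))
    else:
        raise ValueError(f"unknown method {method!r}")
    t_e = min(max(t_e, 1.0), float(M))
    return MultiplicityResult(t_e=t_e, eigenvalues=lam, alpha=alpha)


def significance_tiers(
    p: float, multiplicity: MultiplicityResult, gw_alpha: float = 5e-8
) -> str:
    """Tier a p-value: genome_wide < bonferroni < nominal < none."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if p < gw_alpha:
        return "genome_wide"
    if p < multiplicity.bonferroni_threshold:
        return "bonferroni"
    if p < multiplicity.alpha:
        return "nominal"
    return "none"


def conditional_adjustment(
    pheno: np.ndarray,
    inv_dosage: np.ndarray,
    snp_dosages: pd.DataFrame,
    select_p: float = 5e-8,
    max_steps: int = 20,
    max_r2: float = 0.99,
    inversion_id: str = "inv",
    phenotype_id: str = "pheno",
) -> tuple[list, AssociationResult]:
    """Stepwise SNP selection, then refit the inversion conditionally.

    Forward selection on individual-level data: repeatedly add the
    candidate SNP with the smallest conditional p (given already-selected
    SNPs) while that p is below ``select_p``, skipping candidates whose
    r^2 with the selected set exceeds ``max_r2``; then refit the
    inversion association with the selected SNP dosages as covariates.
    An empty selection reduces to the unconditional fit.
    """
    y = np.asarray(pheno, dtype=float)
    d = np.asarray(inv_dosage, dtype=float)
    n = len(y)
    snp_ids = list(snp_dosages.columns)
    S = snp_dosages.to_numpy(dtype=float)
    selected: list[str] = []
    sel_cols: list[np.ndarray] = []

    for _ in range(max_steps):
        best = None
        base = np.column_stack([np.ones(n)] + sel_cols)
        for j, sid in enumerate(snp_ids):
            if sid in selected:
                continue
            x = S[:, j]
            if sel_cols:
                Z = np.column_stack(sel_cols)
                resid = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
                vx = ((x - x.mean()) ** 2).sum()
                if vx > 0 and 1 - (resid @ resid) / vx > max_r2:
                    continue  # collinear with the selected set
            X = np.column_stack([base, x])
            try:
                _, _, _, pvals, _, _ = _ols(X, y)
            except np.linalg.LinAlgError:
                continue
            pj = pvals[-1]
            if best is None or pj < best[0]:
                best = (pj, sid, x)
        if best is None or best[0] >= select_p:
            break
        selected.append(best[1])
        sel_cols.append(best[2])

    X = np.column_stack([np.ones(n), d] + sel_cols)
    beta, se, t, p, rss, df = _ols(X, y)
    tss = float(((y - y.mean()) ** 2).sum())
    X_red = np.delete(X, 1, axis=1)
    _, _, _, _, rss_red, _ = _ols(X_red, y)
    result = AssociationResult(
        inversion_id=inversion_id,
        phenotype_id=phenotype_id,
        beta=float(beta[1]),
        se=float(se[1]),
        t=float(t[1]),
        p=float(p[1]),
        incremental_r2=max(float((rss_red - rss) / tss), 0.0),
        n=n,
    )
    return selected, result
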