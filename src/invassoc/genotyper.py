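"""Inversion genotype classification from SNP genotype posteriors.

An inversion is treated as a biallelic locus with inverted (I) and
non-inverted (NI) alleles, so a diploid individual is NN, NI or II.
Because recombination is suppressed between orientations, SNPs inside the
inversion region carry family-specific allele frequencies, and an
individual's inversion genotype can be recovered by comparing their SNP
genotypes against per-group genotype frequency tables pre-computed in an
orientation-labelled reference panel.

The similarity score of a sample against inversion-genotype group k is

    H_k = [ sum_i sum_s P_i(s) * f_{k,i}(s) * rho_i^2 ] / [ sum_i p_i^2 ]

where P_i is the sample's genotype posterior at SNP i, p_i = max_s P_i(s)
is the imputation certainty, f_{k,i}(s) the reference frequency of
genotype s in group k, and rho_i^2 the squared haplotype correlation of
SNP i with the inversion orientation.  The called genotype is the argmax
over k, subject to quality control on the number of SNPs used (>= 15 by
default) and on the gap between the top two scores (>= 0.1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("NN", "NI", "II")
_GENO_TO_GROUP = {0: "NN", 1: "NI", 2: "II"}
_GROUP_TO_DOSAGE = {"NN": 0, "NI": 1, "II": 2}

__all__ = [
    "GROUPS",
    "ReferenceModel",
    "SampleGenotypes",
    "InversionCall",
    "TagSNPRule",
    "DegeneratePanelError",
    "NoCallError",
    "build_reference",
    "score_sample",
    "call_genotype",
    "call_cohort",
    "call_by_tag_snp",
    "select_tag_snps",
    "method_concordance",
    "genotype_summary",
]


class DegeneratePanelError(ValueError):
    """Reference panel cannot support classification (single orientation)."""


class NoCallError(ValueError):
    """No usable SNPs shared between a sample and the reference model."""


@dataclass
class SampleGenotypes:
    """One individual's genotype posteriors over an inversion region.

    posteriors is (L, 3): P_i(s) for s in {0, 1, 2}; missing marks SNPs
    with no usable genotype.
    """

    sample_id: str
    snp_ids: list
    posteriors: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        ok = ~self.missing
        if ok.any():
            P = self.posteriors[ok]
            if (P < -1e-12).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(
                    f"sample {self.sample_id}: non-missing posteriors must be "
                    "non-negative and sum to 1"
                )


@dataclass
class ReferenceModel:
    """Per-group genotype frequencies and LD weights for one inversion.

    genotype_freqs has shape (3 groups, L SNPs, 3 genotypes) ordered
    (NN, NI, II) x SNP x (0, 1, 2); weights holds rho_i^2.
    """

    inversion_id: str
    snp_meta: pd.DataFrame  # columns: id, pos, ref, alt
    genotype_freqs: np.ndarray
    weights: np.ndarray
    group_counts: dict
    uniform_groups: tuple = ()

    def __post_init__(self) -> None:
        f = np.asarray(self.genotype_freqs, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        for gi, g in enumerate(GROUPS):
            if self.group_counts.get(g, 0) > 0:
                if not np.allclose(f[gi].sum(axis=1), 1.0, atol=1e-9):
                    raise ValueError(f"group {g}: genotype frequencies must sum to 1 per SNP")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError("LD weights rho^2 must lie in [0, 1]")
        self.genotype_freqs = f
        self.weights = np.clip(w, 0.0, 1.0)

    @property
    def n_snps(self) -> int:
        return len(self.weights)

    @property
    def snp_ids(self) -> list:
        return list(self.snp_meta["id"])


@dataclass
class InversionCall:
    """A classified inversion genotype with QC diagnostics."""

    sample_id: str
    inversion_id: str
    scores: dict  # group -> H_k
    called_genotype: str  # NN / NI / II / missing
    dosage: object  # 0/1/2 or None
    n_snps_used: int
    score_diff: float
    qc_pass: bool
    qc_flags: dict = field(default_factory=dict)


@dataclass
class TagSNPRule:
    """Call an inversion from a single high-LD tag SNP."""

    inversion_id: str
    snp_id: str
    inverted_allele: str
    alt_allele: str
    r2: float = 1.0
    min_r2: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.min_r2 <= 1.0:
            raise ValueError(f"min_r2 must be in (0, 1], got {self.min_r2}")


def _orientation_r2(panel) -> np.ndarray:
    """Squared Pearson correlation of each SNP with orientation, plus sign."""
    inv = (np.asarray(panel.orientation) == "I").astype(float)
    H = panel.haplotypes.astype(float)
    inv_c = inv - inv.mean()
    H_c = H - H.mean(axis=0)
    denom = np.sqrt((inv_c**2).sum() * (H_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (H_c * inv_c[:, None]).sum(axis=0) / denom
    r = np.nan_to_num(r, nan=0.0)  # monomorphic SNP or degenerate panel -> no information
    return r


def build_reference(panel, inversion_id: str | None = None) -> ReferenceModel:
    """Pre-compute group genotype frequencies and LD weights from a panel.

    f_{k,i}(s) is the raw empirical frequency of diploid genotype s among
    reference individuals of inversion genotype k (no smoothing; empty
    groups get a uniform table and are flagged).  rho_i^2 is the squared
    haplotype correlation between the SNP alt-allele indicator and the
    inverted-orientation indicator.
    """
    orient = np.asarray(panel.orientation)
    if len(set(orient)) < 2:
        raise DegeneratePanelError(
            "all reference haplotypes share one orientation; cannot classify"
        )
    inversion_id = inversion_id or getattr(panel, "inversion_id", "inv")
    geno = panel.individual_genotypes()  # (N, L)
    inv_geno = panel.individual_inv_genotypes()  # (N,)
    L = geno.shape[1]

    freqs = np.full((3, L, 3), 1.0 / 3.0)
    counts = {}
    uniform = []
    for gi, g in enumerate(GROUPS):
        members = geno[inv_geno == gi]
        counts[g] = len(members)
        if len(members) == 0:
            uniform.append(g)
            continue
        for s in (0, 1, 2):
            freqs[gi, :, s] = (members == s).mean(axis=0)

    r = _orientation_r2(panel)
    meta = panel.snp_meta[["id", "pos", "ref", "alt"]].copy()
    meta["orientation_r"] = r
    return ReferenceModel(
        inversion_id=inversion_id,
        snp_meta=meta,
        genotype_freqs=freqs,
        weights=r**2,
        group_counts=counts,
        uniform_groups=tuple(uniform),
    )


def score_sample(
    sample: SampleGenotypes,
    ref: ReferenceModel,
    normalization: str = "max_posterior",
) -> tuple[dict, int]:
    """Similarity scores H_k of one sample against the reference model.

    Only SNPs that are non-missing in the sample and present in the
    reference enter the sums; they are excluded from both numerator and
    denominator.  ``normalization`` selects the denominator: the default
    "max_posterior" uses sum_i p_i^2 with p_i the max posterior; the
    alternative "weighted" uses sum_i p_i * rho_i^2.

    Returns ({group: H_k}, n_snps_used).
    """
    ref_index = {s: i for i, s in enumerate(ref.snp_ids)}
    sample_idx, ref_idx = [], []
    for j, sid in enumerate(sample.snp_ids):
        if not sample.missing[j] and sid in ref_index:
            sample_idx.append(j)
            ref_idx.append(ref_index[sid])
    if not sample_idx:
        raise NoCallError(f"sample {sample.sample_id}: no usable SNPs shared with reference")

    P = sample.posteriors[sample_idx]  # (U, 3)
    w = ref.weights[ref_idx]  # (U,)
    F = ref.genotype_freqs[:, ref_idx, :]  # (3, U, 3)
    p_max = P.max(axis=1)

    numer = np.einsum("us,kus,u->k", P, F, w)
    if normalization == "max_posterior":
        denom = float((p_max**2).sum())
    elif normalization == "weighted":
        denom = float((p_max * w).sum())
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom == 0.0:
        raise NoCallError(f"sample {sample.sample_id}: zero score denominator")
    scores = {g: float(numer[gi] / denom) for gi, g in enumerate(GROUPS)}
    return scores, len(sample_idx)


def call_genotype(
    scores: dict,
    n_snps_used: int,
    sample_id: str = "",
    inversion_id: str = "",
    min_snps: int = 15,
    min_diff: float = 0.1,
) -> InversionCall:
    """Apply QC and assign the argmax group, or a no-call.

    A call requires at least ``min_snps`` SNPs used and a gap of at least
    ``min_diff`` between the top two scores; an exact tie on the top score
    is a no-call regardless of min_diff.
    """
    vals = np.array([scores[g] for g in GROUPS], dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite")
    order = np.argsort(vals)[::-1]
    top, second = vals[order[0]], vals[order[1]]
    diff = float(top - second)
    flags = {
        "min_snps": n_snps_used >= min_snps,
        "min_diff": diff >= min_diff,
        "tie": diff == 0.0,
    }
    ok = flags["min_snps"] and flags["min_diff"] and not flags["tie"]
    if ok:
        g = GROUPS[order[0]]
        dosage = _GROUP_TO_DOSAGE[g]
    else:
        g, dosage = "missing", None
    return InversionCall(
        sample_id=sample_id,
        inversion_id=inversion_id,
        scores=dict(scores),
        called_genotype=g,
        dosage=dosage,
        n_snps_used=n_snps_used,
        score_diff=diff,
        qc_pass=ok,
        qc_flags=flags,
    )


def call_cohort(
    cohort: list,
    ref: ReferenceModel,
    min_snps: int = 15,
    min_diff: float = 0.1,
    normalization: str = "max_posterior",
) -> tuple[list, float]:
    """Score and call every sample; returns (calls, callability)."""
    if not cohort:
        raise ValueError("empty cohort")
    calls = []
    for sample in cohort:
        try:
            scores, n_used = score_sample(sample, ref, normalization=normalization)
        except NoCallError:
            calls.append(
                InversionCall(
                    sample_id=sample.sample_id,
                    inversion_id=ref.inversion_id,
                    scores={g: float("nan") for g in GROUPS},
                    called_genotype="missing",
                    dosage=None,
                    n_snps_used=0,
                    score_diff=0.0,
                    qc_pass=False,
                    qc_flags={"min_snps": False, "min_diff": False, "tie": False},
                )
            )
            continue
        calls.append(
            call_genotype(
                scores,
                n_used,
                sample_id=sample.sample_id,
                inversion_id=ref.inversion_id,
                min_snps=min_snps,
                min_diff=min_diff,
            )
        )
    callability = sum(c.qc_pass for c in calls) / len(calls)
    return calls, callability


def call_by_tag_snp(sample: SampleGenotypes, rule: TagSNPRule) -> str:
    """Read the inversion genotype off a single tag SNP.

    The posterior-argmax genotype at the tag SNP gives the count of the
    SNP's alt allele; that count is converted to a count of the inverted
    allele and mapped 0 -> NN, 1 -> NI, 2 -> II.  A missing or unknown
    tag SNP yields "missing".
    """
    try:
        j = sample.snp_ids.index(rule.snp_id)
    except ValueError:
        return "missing"
    if sample.missing[j]:
        return "missing"
    alt_count = int(np.argmax(sample.posteriors[j]))
    inv_count = alt_count if rule.inverted_allele == rule.alt_allele else 2 - alt_count
    return _GENO_TO_GROUP[inv_count]


def select_tag_snps(panel, min_r2: float = 0.9) -> list:
    """SNPs in LD r^2 >= min_r2 with the orientation, best first.

    Each rule records the allele phased with the inverted orientation:
    the alt allele when the haplotype correlation is positive, else the
    ref allele.
    """
    r = _orientation_r2(panel)
    r2 = r**2
    rules = []
    for i in np.argsort(r2)[::-1]:
        if r2[i] < min_r2:
            break
        row = panel.snp_meta.iloc[i]
        rules.append(
            TagSNPRule(
                inversion_id=getattr(panel, "inversion_id", "inv"),
                snp_id=row["id"],
                inverted_allele=row["alt"] if r[i] > 0 else row["ref"],
                alt_allele=row["alt"],
                r2=float(r2[i]),
                min_r2=min_r2,
            )
        )
    return rules


def method_concordance(calls_a: dict, calls_b: dict) -> tuple[float, int]:
    """Fraction of samples called by both methods with identical genotype.

    Arguments map sample_id -> genotype string ("missing" excluded).
    """
    shared = [
        s
        for s in calls_a
        if s in calls_b and calls_a[s] != "missing" and calls_b[s] != "missing"
    ]
    if not shared:
        raise ValueError("no samples called by both methods; accuracy undefined")
    agree = sum(calls_a[s] == calls_b[s] for s in shared)
    return agree / len(shared), len(shared)


def genotype_summary(calls: list) -> tuple[float, float, dict]:
    """Inverted-allele frequency and HWE test over QC-passing calls.

    The chi-square HWE goodness-of-fit test (1 df) compares observed
    genotype counts to p^2 / 2pq / q^2 at the estimated allele frequency.
    """
    passing = [c for c in calls if c.qc_pass]
    if not passing:
        raise ValueError("no QC-passing calls to summarize")
    counts = {g: 0 for g in GROUPS}
    for c in passing:
        counts[c.called_genotype] += 1
    n = len(passing)
    q = (counts["NI"] + 2 * counts["II"]) / (2 * n)
    p = 1.0 - q
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([counts[g] for g in GROUPS], dtype=float)
    if q in (0.0, 1.0):
        return q, 1.0, counts  # monomorphic: HWE trivially satisfied
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum((observed - expected) ** 2 / expected)
    hwe_p = float(stats.chi2.sf(chi2, df=1))
    return q, hwe_p, counts
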