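"""Synthetic reference panels, imputed cohorts, and phenotypes.

Chromosomal inversions suppress recombination between the inverted (I) and
non-inverted (NI) orientations, so the two orientations behave as diverged
haplotype families with family-specific SNP allele frequencies.  The
generator emulates exactly the structure the downstream classifier relies
on: two haplotype families whose per-SNP allele frequencies are separated
by a configurable divergence, Hardy-Weinberg diploids at a stated inversion
allele frequency, per-SNP imputation certainty, and phenotypes with
additive inversion effects on top of covariates and a global-size
component.

Sites are independent conditional on family membership: the classifier
uses only per-SNP frequencies, so richer within-family LD would complicate
oracles without exercising any additional code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyper import SampleGenotypes

__all__ = [
    "SimulationConfig",
    "HaplotypePanel",
    "CohortSim",
    "simulate_reference_panel",
    "simulate_cohort",
    "simulate_phenotypes",
    "simulate_two_cohorts",
]


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig fails validation."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a single 17q21.31-like locus: inversion allele
    frequency ~0.2 in Europeans, a 503-individual reference panel, strong
    family divergence (recombination suppression), and high imputation
    certainty.

    Parameters
    ----------
    seed
        Master seed; identical config + seed gives bit-identical output.
    n_ref_individuals
        Diploid individuals in the phased reference panel.
    n_study
        Individuals in the imputed study cohort.
    n_snps
        SNPs per inversion region (L).
    inv_freq
        Population frequency q of the inverted allele.
    divergence
        Per-SNP allele-frequency separation delta between the I and NI
        haplotype families, in [0, 0.5].  The I family gets pi + delta,
        the NI family pi - delta (clipped to [0.01, 0.99]).
    genotype_error_rate
        Probability epsilon that an observed genotype is perturbed to an
        adjacent dosage value.
    certainty_model
        ("constant", c) or ("beta", a, b): per-SNP max-posterior
        certainty p_i in (0, 1].
    n_inversions
        Number of independently simulated inversion loci.
    betas
        (n_inversions, n_phenotypes) additive effects of inverted-allele
        dosage on each phenotype, in phenotype units per allele.
    n_phenotypes
        Regional phenotypes emitted.
    phenotype_corr
        Target correlation matrix of the phenotype noise (unit diagonal,
        symmetric PSD); None means identity.
    global_weight
        Loading of the global measure g on every regional phenotype.
    x_linked_flags
        Per-inversion booleans; x-linked loci give males one haplotype.
    sex_ratio
        Probability that an individual is male.
    """

    seed: int = 0
    n_ref_individuals: int = 503
    n_study: int = 2000
    n_snps: int = 30
    inv_freq: float = 0.2
    divergence: float = 0.45
    genotype_error_rate: float = 0.0
    certainty_model: tuple = ("beta", 99.0, 1.0)
    n_inversions: int = 1
    betas: np.ndarray | None = None
    n_phenotypes: int = 4
    phenotype_corr: np.ndarray | None = None
    global_weight: float = 0.0
    x_linked_flags: tuple = ()
    sex_ratio: float = 0.5
    gamma_age: float = 0.0
    gamma_sex: float = 0.0
    n_sites: int = 2
    dc_mode: str = "full_dc"

    def __post_init__(self) -> None:
        for name in ("n_ref_individuals", "n_study", "n_snps", "n_inversions", "n_phenotypes"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("inv_freq", "genotype_error_rate", "sex_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.divergence <= 0.5:
            raise ConfigurationError(f"divergence must be in [0, 0.5], got {self.divergence}")
        if self.certainty_model[0] not in ("constant", "beta"):
            raise ConfigurationError(f"unknown certainty model {self.certainty_model[0]!r}")
        if self.dc_mode not in ("full_dc", "no_dc"):
            raise ConfigurationError(f"dc_mode must be full_dc or no_dc, got {self.dc_mode!r}")
        if self.betas is not None:
            self.betas = np.asarray(self.betas, dtype=float)
            if self.betas.shape != (self.n_inversions, self.n_phenotypes):
                raise ConfigurationError(
                    f"betas shape {self.betas.shape} != "
                    f"({self.n_inversions}, {self.n_phenotypes})"
                )
        if self.phenotype_corr is not None:
            C = np.asarray(self.phenotype_corr, dtype=float)
            if C.shape != (self.n_phenotypes, self.n_phenotypes):
                raise ConfigurationError("phenotype_corr has wrong shape")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ConfigurationError("phenotype_corr must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ConfigurationError("phenotype_corr must have unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise ConfigurationError("phenotype_corr must be positive semi-definite")
            self.phenotype_corr = C
        if self.x_linked_flags and len(self.x_linked_flags) != self.n_inversions:
            raise ConfigurationError("x_linked_flags length must equal n_inversions")

    def x_linked(self, m: int) -> bool:
        return bool(self.x_linked_flags[m]) if self.x_linked_flags else False

    def rng(self, *stream: int) -> np.random.Generator:
        """A generator for a named sub-stream, reproducible from the seed."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), *stream]))


@dataclass
class HaplotypePanel:
    """A phased reference panel with per-haplotype orientation labels.

    haplotypes is a (2 * n_individuals, L) binary matrix of alt-allele
    indicators; orientation holds "I"/"NI" per haplotype; diploid_pairing
    maps each individual to its two haplotype row indices.
    """

    snp_meta: pd.DataFrame  # columns: id, chrom, pos, ref, alt
    haplotypes: np.ndarray
    orientation: np.ndarray
    diploid_pairing: np.ndarray
    inversion_id: str = "inv"

    def __post_init__(self) -> None:
        H = np.asarray(self.haplotypes)
        if not np.isin(H, (0, 1)).all():
            raise ValueError("haplotype matrix entries must be 0/1")
        if len(self.orientation) != H.shape[0]:
            raise ValueError("orientation must label every haplotype")
        pos = self.snp_meta["pos"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError("SNP positions must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return self.diploid_pairing.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def individual_genotypes(self) -> np.ndarray:
        """(n_individuals, L) alt-allele dosages."""
        return (
            self.haplotypes[self.diploid_pairing[:, 0]]
            + self.haplotypes[self.diploid_pairing[:, 1]]
        )

    def individual_inv_genotypes(self) -> np.ndarray:
        """(n_individuals,) inverted-allele dosages (0=NN, 1=NI, 2=II)."""
        inv = (self.orientation == "I").astype(int)
        return inv[self.diploid_pairing[:, 0]] + inv[self.diploid_pairing[:, 1]]


@dataclass
class CohortSim:
    """One simulated study cohort for a set of inversion loci."""

    sample_ids: list
    sex: np.ndarray  # 1 = male, 0 = female
    truth: pd.DataFrame  # samples x inversions, inverted-allele counts
    genotypes: dict  # inversion_id -> list[SampleGenotypes]
    panels: dict = field(default_factory=dict)  # inversion_id -> HaplotypePanel


def _snp_meta(config: SimulationConfig, inversion_id: str, chrom: str = "1") -> pd.DataFrame:
    L = config.n_snps
    return pd.DataFrame(
        {
            "id": [f"{inversion_id}_snp{i:04d}" for i in range(L)],
            "chrom": chrom,
            "pos": np.arange(1, L + 1) * 100 + 1000,
            "ref": "A",
            "alt": "G",
        }
    )


def _family_freqs(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequencies on the I and NI families for each SNP."""
    base = rng.uniform(0.05, 0.95, size=config.n_snps)
    f_inv = np.clip(base + config.divergence, 0.01, 0.99)
    f_std = np.clip(base - config.divergence, 0.01, 0.99)
    return f_inv, f_std


def simulate_reference_panel(
    config: SimulationConfig, inversion_index: int = 0
) -> HaplotypePanel:
    """Simulate a phased, orientation-labelled reference panel.

    Each haplotype's orientation is Bernoulli(q); conditional on
    orientation, SNP alleles are independent Bernoulli draws at the
    family-specific frequency.  Haplotypes are paired at random into
    diploid individuals.
    """
    rng = config.rng(0, inversion_index)
    inversion_id = f"inv{inversion_index:02d}"
    n_hap = 2 * config.n_ref_individuals
    f_inv, f_std = _family_freqs(config, rng)
    orientation_bits = rng.random(n_hap) < config.inv_freq
    freqs = np.where(orientation_bits[:, None], f_inv[None, :], f_std[None, :])
    haplotypes = (rng.random((n_hap, config.n_snps)) < freqs).astype(np.int8)
    pairing = rng.permutation(n_hap).reshape(config.n_ref_individuals, 2)
    orientation = np.where(orientation_bits, "I", "NI")
    return HaplotypePanel(
        snp_meta=_snp_meta(config, inversion_id, chrom=str(inversion_index + 1)),
        haplotypes=haplotypes,
        orientation=orientation,
        diploid_pairing=pairing,
        inversion_id=inversion_id,
    )


def _draw_certainty(config: SimulationConfig, rng: np.random.Generator, size) -> np.ndarray:
    kind = config.certainty_model[0]
    if kind == "constant":
        return np.full(size, float(config.certainty_model[1]))
    a, b = config.certainty_model[1], config.certainty_model[2]
    p = rng.beta(a, b, size=size)
    # certainty below 1/3 would not even be the max posterior of a 3-class vector
    return np.clip(p, 0.34, 1.0)


def _perturb_adjacent(g: np.ndarray, flip: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Move flipped genotypes to an adjacent dosage: 0->1, 2->1, 1->0 or 2."""
    out = g.copy()
    het = flip & (g == 1)
    out[flip & (g == 0)] = 1
    out[flip & (g == 2)] = 1
    out[het] = rng.choice([0, 2], size=int(het.sum()))
    return out


def simulate_cohort(config: SimulationConfig) -> CohortSim:
    """Simulate an imputed study cohort with per-SNP genotype posteriors.

    True inversion genotypes come from two independent Bernoulli(q)
    haplotype draws (one for males at x-linked loci); observed SNP
    genotypes equal the family-consistent draw with probability
    1 - epsilon, else an adjacent dosage; each SNP carries a posterior
    vector placing mass p_i on the observed genotype and (1 - p_i)/2 on
    each of the other two.
    """
    n = config.n_study
    sample_ids = [f"S{i:05d}" for i in range(n)]
    sex = (config.rng(9).random(n) < config.sex_ratio).astype(int)
    truth = {}
    genotypes = {}
    panels = {}
    for m in range(config.n_inversions):
        panel = simulate_reference_panel(config, inversion_index=m)
        panels[panel.inversion_id] = panel
        rng = config.rng(1, m)
        # reuse the panel's family frequencies so study and reference agree
        f_inv, f_std = _family_freqs(config, config.rng(0, m))

        hap1 = rng.random(n) < config.inv_freq
        hap2 = rng.random(n) < config.inv_freq
        if config.x_linked(m):
            inv_dosage = np.where(sex == 1, hap1.astype(int), hap1.astype(int) + hap2.astype(int))
        else:
            inv_dosage = hap1.astype(int) + hap2.astype(int)
        truth[panel.inversion_id] = inv_dosage

        L = config.n_snps
        a1 = (rng.random((n, L)) < np.where(hap1[:, None], f_inv, f_std)).astype(int)
        a2 = (rng.random((n, L)) < np.where(hap2[:, None], f_inv, f_std)).astype(int)
        if config.x_linked(m):
            # hemizygous males are represented on the diploid scale (0 or 2)
            geno = np.where((sex == 1)[:, None], 2 * a1, a1 + a2)
        else:
            geno = a1 + a2

        flip = rng.random((n, L)) < config.genotype_error_rate
        observed = _perturb_adjacent(geno, flip, rng)
        certainty = _draw_certainty(config, rng, (n, L))

        post = np.empty((n, L, 3))
        post[:] = ((1.0 - certainty) / 2.0)[:, :, None]
        np.put_along_axis(post, observed[:, :, None], certainty[:, :, None], axis=2)

        samples = [
            SampleGenotypes(
                sample_id=sample_ids[j],
                snp_ids=list(panel.snp_meta["id"]),
                posteriors=post[j],
                missing=np.zeros(L, dtype=bool),
            )
            for j in range(n)
        ]
        genotypes[panel.inversion_id] = samples

    truth_df = pd.DataFrame(truth, index=sample_ids)
    return CohortSim(
        sample_ids=sample_ids, sex=sex, truth=truth_df, genotypes=genotypes, panels=panels
    )


def simulate_phenotypes(
    truth_dosages: pd.DataFrame,
    config: SimulationConfig,
    sex: np.ndarray | None = None,
    betas: np.ndarray | None = None,
    rng_stream: int = 2,
):
    """Generate phenotypes with additive inversion effects and covariates.

    y_j = sum_m beta_{m,j} * dosage_m + gamma_age*age + gamma_sex*sex
          + global_weight*g + e,  e ~ N(0, phenotype_corr).

    For x-linked inversions the dosage entering the generative model
    follows ``config.dc_mode``: full_dc doubles the male hemizygous
    allele count, no_dc leaves it at {0, 1}.

    Returns a PhenotypeTable (see :mod:`invassoc.association`).
    """
    from .association import PhenotypeTable

    D = truth_dosages.to_numpy(dtype=float)
    n, n_inv = D.shape
    if betas is None:
        betas = config.betas
    if betas is None:
        betas = np.zeros((n_inv, config.n_phenotypes))
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (n_inv, config.n_phenotypes):
        raise ValueError(
            f"betas shape {betas.shape} incompatible with "
            f"({n_inv} inversions, {config.n_phenotypes} phenotypes)"
        )

    rng = config.rng(rng_stream)
    if sex is None:
        sex = (rng.random(n) < config.sex_ratio).astype(int)
    sex = np.asarray(sex)

    # generative dosage respects the configured X dosage-compensation mode
    D_eff = D.copy()
    for m in range(n_inv):
        if config.x_linked(m) and config.dc_mode == "full_dc":
            D_eff[sex == 1, m] = 2.0 * D_eff[sex == 1, m]

    age = rng.normal(55.0, 7.5, size=n)
    site = rng.integers(0, config.n_sites, size=n)
    quality = rng.normal(0.0, 1.0, size=n)
    g = rng.normal(0.0, 1.0, size=n)

    C = config.phenotype_corr
    if C is None:
        e = rng.standard_normal((n, config.n_phenotypes))
    else:
        chol = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
        e = rng.standard_normal((n, config.n_phenotypes)) @ chol.T

    y = (
        D_eff @ betas
        + config.gamma_age * age[:, None]
        + config.gamma_sex * sex[:, None]
        + config.global_weight * g[:, None]
        + e
    )

    ids = list(truth_dosages.index)
    pheno = pd.DataFrame(
        y, index=ids, columns=[f"pheno{j:02d}" for j in range(config.n_phenotypes)]
    )
    covars = pd.DataFrame(
        {"age": age, "sex": sex, "site": site, "quality": quality, "diagnosis": 0},
        index=ids,
    )
    globals_df = pd.DataFrame({"global": g}, index=ids)
    global_map = {c: "global" for c in pheno.columns}
    return PhenotypeTable(
        phenotypes=pheno, covariates=covars, global_measures=globals_df, global_map=global_map
    )


def plant_perfect_tag(
    panel: HaplotypePanel,
    cohort: CohortSim,
    snp_index: int = 0,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Turn one SNP into a perfect tag of the inversion (r^2 = 1).

    Overwrites the panel haplotype column with the orientation indicator
    and each study sample's posterior at that SNP with a point mass on
    the true inverted-allele dosage (perturbed to an adjacent dosage
    with probability ``error_rate``, matching the cohort's genotype
    error process).  Returns the matching TagSNPRule.
    """
    from .genotyper import TagSNPRule

    inv_id = panel.inversion_id
    panel.haplotypes[:, snp_index] = (panel.orientation == "I").astype(np.int8)
    truth = cohort.truth[inv_id].to_numpy()
    observed = truth.copy()
    if error_rate > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        flip = rng.random(len(observed)) < error_rate
        observed = _perturb_adjacent(observed, flip, rng)
    for j, s in enumerate(cohort.genotypes[inv_id]):
        s.posteriors[snp_index] = 0.0
        s.posteriors[snp_index, observed[j]] = 1.0
        s.missing[snp_index] = False
    row = panel.snp_meta.iloc[snp_index]
    return TagSNPRule(
        inversion_id=inv_id,
        snp_id=row["id"],
        inverted_allele=row["alt"],
        alt_allele=row["alt"],
        r2=1.0,
    )


def simulate_two_cohorts(
    config: SimulationConfig, beta_corr: float, beta_sd: float = 0.1
) -> tuple[tuple[CohortSim, "object"], tuple[CohortSim, "object"], np.ndarray, np.ndarray]:
    """Two independent cohorts whose true effects are correlated.

    True per-(inversion, phenotype) effects (beta_d, beta_r) are drawn
    from a bivariate normal with correlation ``beta_corr`` and marginal
    sd ``beta_sd``; everything else follows simulate_cohort /
    simulate_phenotypes with independent randomness per cohort.

    Returns ((cohort_d, pheno_d), (cohort_r, pheno_r), betas_d, betas_r).
    """
    if not -1.0 <= beta_corr <= 1.0:
        raise ConfigurationError(f"beta_corr must be in [-1, 1], got {beta_corr}")
    rng = config.rng(3)
    k = config.n_inversions * config.n_phenotypes
    cov = beta_sd**2 * np.array([[1.0, beta_corr], [beta_corr, 1.0]])
    draws = rng.multivariate_normal(np.zeros(2), cov, size=k)
    betas_d = draws[:, 0].reshape(config.n_inversions, config.n_phenotypes)
    betas_r = draws[:, 1].reshape(config.n_inversions, config.n_phenotypes)

    import dataclasses

    cfg_d = dataclasses.replace(config, seed=int(config.rng(4).integers(2**31)))
    cfg_r = dataclasses.replace(config, seed=int(config.rng(5).integers(2**31)))
    cohort_d = simulate_cohort(cfg_d)
    cohort_r = simulate_cohort(cfg_r)
    pheno_d = simulate_phenotypes(cohort_d.truth, cfg_d, sex=cohort_d.sex, betas=betas_d)
    pheno_r = simulate_phenotypes(cohort_r.truth, cfg_r, sex=cohort_r.sex, betas=betas_r)
    return (cohort_d, pheno_d), (cohort_r, pheno_r), betas_d, betas_r
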