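# Methods

## The problem

Common chromosomal inversions (17q21.31, 8p23.1, 16p11.2, ...) suppress
recombination between the inverted (I) and non-inverted (NI)
orientations. The two orientations therefore segregate as diverged
haplotype families with family-specific SNP allele frequencies inside
the inverted segment, which makes the inversion genotype of a diploid
individual (NN, NI, II) recoverable from ordinary SNP genotypes.
`invassoc` implements that recovery and the downstream
genotype-phenotype association machinery, and ships a synthetic-data
generator so every stage is testable without any individual-level data
download.

## Similarity-score genotyping

For each inversion a reference model is pre-computed from a phased,
orientation-labelled panel: the empirical frequency f_k,i(s) of diploid
genotype s ∈ {0,1,2} at SNP i among reference individuals of inversion
genotype k ∈ {NN, NI, II}, and a per-SNP LD weight ρ_i², the squared
Pearson correlation across haplotypes between the SNP's alt-allele
indicator and the inverted-orientation indicator. A study individual
with genotype posterior P_i(·) at SNP i is scored against each group:

    H_k = [ Σ_i Σ_s P_i(s) · f_k,i(s) · ρ_i² ] / [ Σ_i p_i² ],

with p_i = max_s P_i(s) the imputation certainty. SNPs missing in the
sample (or absent from the reference) are excluded from both numerator
and denominator. The called genotype is argmax_k H_k, subject to two
QC rules with defaults min_snps = 15 (SNP call rate) and min_diff = 0.1
(gap between the top two scores); a failed rule or an exact top-score
tie yields a no-call rather than an arbitrary assignment, since a tie
cannot satisfy any positive score gap and argmax tie-breaking would be
order-dependent.

Numerical/design choices:

- The denominator Σ p_i² is implemented exactly as the method defines
  it. Because that normalization is unusual (it ignores the LD
  weights), `score_sample(..., normalization="weighted")` offers
  Σ p_i·ρ_i² as an alternative; the default is the canonical form, and
  the two agree on which group maximizes H_k because the denominator is
  group-independent.
- Frequency tables are raw empirical frequencies with no pseudocount:
  a genotype unseen in a reference group contributes exactly zero, and
  a group with no reference individuals gets a uniform table and is
  flagged (`uniform_groups`).
- Tag-SNP calls use the posterior-argmax genotype (not expected
  dosage), because concordance between calling methods needs
  categorical genotypes. The rule records which allele is phased with
  the inverted orientation, so a tag whose *ref* allele tags the
  inversion is handled by reversing the dosage.
- Coordinates are 1-based inclusive (VCF convention); multi-allelic or
  half-missing genotypes are treated as missing at that SNP.

`select_tag_snps` replaces the original tag-discovery GWAS with direct
haplotype LD screening (r² ≥ 0.9 against orientation), which is the
quantity that GWAS was measuring.

## Synthetic data

The generator emulates exactly the structure the classifier exploits
and nothing more:

- Two haplotype families. Each reference haplotype is I with
  probability q (default 0.2, a 17q21.31-like European frequency) and
  carries independent Bernoulli alleles at family-specific frequencies
  π_i ± δ (clipped to [0.01, 0.99]), π_i ~ U(0.05, 0.95). Sites are
  independent conditional on family: the classifier only consumes
  per-SNP frequencies, so intra-family LD would complicate test oracles
  without exercising any code path. There is no coalescent realism,
  recombination map, or demography.
- Family divergence δ defaults to 0.45. The divergence controls how
  separable the families are and hence the no-call rate; at 0.45 the
  default cohort reproduces the operating point the method is reported
  to have in practice (under 1% of subjects failing the score-gap QC),
  while δ = 0.40 would leave ~9% uncalled and δ = 0.49 makes every
  locus trivially separable.
- Study cohorts. Each individual draws two Bernoulli(q) haplotypes
  (one for males at X-linked loci), so true inversion genotypes are
  Hardy-Weinberg. Observed SNP genotypes equal the family-consistent
  draw with probability 1 − ε, otherwise move to an *adjacent* dosage
  (0↔1, 2↔1; from 1 to either side with equal probability), mimicking
  single-allele miscalls. Per-SNP certainty p_i comes from the
  configured distribution — default Beta(99, 1), mean ≈ 0.99, i.e.
  well-imputed data; the true certainty distribution of biobank
  imputation is not published, so this is a modelling choice, not a
  claim — and the emitted posterior puts mass p_i on the observed
  genotype and (1 − p_i)/2 on each other genotype.
- Phenotypes. y_j = Σ_m β_mj·d_m + γ_age·age + γ_sex·sex +
  w_g·g + e with e ~ N(0, C) for a target correlation C (Cholesky
  factorization), a standard-normal global measure g, and covariates
  (age, sex, site, quality proxy) emitted alongside. For X-linked loci
  the generative dosage follows the configured dosage-compensation mode
  (full DC doubles male hemizygous counts).
- Determinism. All randomness flows from `numpy` `SeedSequence`
  streams keyed by (seed, stage), so identical configs give
  bit-identical panels, cohorts, and phenotypes, and study and
  reference draws share the same family frequencies.

What passing tests on these data do *not* show: robustness to
intra-family LD structure, reference-panel ancestry mismatch, imputation
artefacts correlated across SNPs, or assortative structure in real
cohorts.

## Association pipeline

- Genotype QC: drop individuals with >10% missing SNPs, then SNPs with
  >5% missingness, HWE p < 1e-6 (1-df chi-square goodness of fit), or
  MAF < 0.01, counted in that order.
- Relatedness: GRM A_jk = (1/M) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) /
  (2p_i(1 − p_i)); pairs with A > 0.1 are pruned greedily, repeatedly
  removing the individual in the most over-threshold pairs (ties to the
  larger index). Greedy-by-degree retains the maximum number of
  samples on pair and triangle structures; optimal vertex cover is not
  attempted.
- Residualization: per-phenotype OLS on age, sex, site (fixed-effect
  indicator contrasts, no random effects), quality proxy, and any
  further covariate columns (e.g. a diagnosis flag); with
  `adjust_global`, the phenotype's mapped global measure (total area /
  mean thickness / intracranial volume analogue) joins the design. A
  rank-deficient design is an error naming the collinear columns.
- Inverse normal transformation: Blom variant,
  Φ⁻¹((r − 3/8)/(n + 1/4)) with average ranks for ties. The offset
  choice is conventional; any offset preserves the weak ordering and a
  standard-normal marginal.
- Joint regression: each transformed phenotype on *all* inversion
  dosages simultaneously plus an intercept; per-inversion β, SE,
  two-sided t-test, and incremental R² = R²(full) − R²(full minus that
  inversion). The OLS core is plain linear algebra for speed in the
  Monte-Carlo suites and is pinned to `statsmodels.OLS` results in the
  tests.
- X coding: male hemizygotes enter as {0,2} under full dosage
  compensation or {0,1} under none; both codings are run as a
  sensitivity analysis since the truth is unidentifiable at realistic
  power.
- Multiplicity: effective number of independent phenotypes t_e from
  the eigenvalues λ of the phenotype correlation matrix. Default is
  the Li-Ji estimator Σ_i [1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)] (eigenvalues
  within 1e-9 of an integer are snapped before flooring, since ⌊·⌋ is
  discontinuous); the Nyholt variant 1 + (M−1)(1 − var(λ)/M) is
  available by option. Tiers: genome-wide p < 5e-8, then Bonferroni
  p < α/t_e, then nominal p < 0.05.
- Conditional adjustment: individual-level forward stepwise selection
  over region SNPs (add the smallest conditional p while it is below
  5e-8, at most 20 steps, skipping candidates with r² > 0.99 against
  the already-selected set), then refit the inversion with the selected
  SNPs as covariates. This reproduces the logic of summary-statistic
  conditional-and-joint analysis in the individual-level setting where
  no LD reference panel is needed.

## Generalization statistics

Pairs nominally significant in discovery (p < 0.05, discovery only) are
joined to replication estimates. The raw Pearson correlation of betas
is attenuated by estimation noise, so an error-adjusted correlation
divides cov(β_d, β_r) by √[(var(β_d) − mean(se_d²)) · (var(β_r) −
mean(se_r²))] — method-of-moments disattenuation — clamped to [−1, 1]
and flagged undefined if a corrected variance is non-positive. How the
original analysis adjusted for estimation error is not specified beyond
"accounting for errors"; disattenuation by mean squared SE is the
simplest estimator with the right expectation. Sign concordance counts
pairs with agreeing effect signs (exact zeros discordant, conservative)
and tests k of n against 0.5 with an exact one-sided binomial test
(two-sided by option).

## Problem sizes and calibration studies

The bundled studies (in `invassoc.studies`, exercised by the analysis
drivers, the test suite, and `scripts/acceptance.py`) use: cohorts of
n = 2,000 for genotyping checks (binomial SE on an allele frequency
≈ 0.006); 5,000 null simulations at n = 500 for pipeline type-I error
(99% binomial band 0.041–0.059 around 0.05); 200 replicates at
n = 5,000 for effect recovery (a planted standardized effect of 0.2 is
expected to read back as 0.2/√1.04 ≈ 0.196 after the INT forces unit
variance on signal plus noise); 15–25 replicates at n = 5,000 for
conditional absorption (a tag SNP at r² ≈ 0.98 leaves noncentrality
≈ 1.6, so the *median* conditional p is the stable summary — single
replicates straddle 0.05 by design of the scenario, which is why the
absorption checks assert the median); and 200 replicates of 30 pairs
for disattenuation recovery.

## Known limitations

- The haplotype model has no intra-family LD, so ρ_i² weights are the
  only LD the classifier ever sees; real panels have redundant SNPs.
- Inversion loci are simulated independently (no inter-locus LD),
  consistent with inversion signals being confined to their regions.
- Multi-orientation loci (more than two haplotype families, e.g.
  3q26.1-like) are not modelled; in practice they fail the score-gap
  QC, which is how the real analysis excluded them.
- The greedy relatedness filter is heuristic; pathological relatedness
  graphs could be pruned sub-optimally.
- `beta_correlation`'s disattenuation assumes independent pairs;
  effects sharing an inversion are in fact correlated, so its p-value
  applies to the raw, not the adjusted, correlation.
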