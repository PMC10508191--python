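"""End-to-end orchestration: simulate -> build-ref -> call -> associate.

run_pipeline stitches the stages together and writes a results bundle:
a calls TSV (per sample x inversion: similarity scores, genotype,
dosage, QC), an association TSV (per inversion x phenotype: beta, se, t,
p, incremental r^2, significance tier), a multiplicity JSON (effective
test count and Bonferroni level), an optional generalization JSON, and a
run log recording the seed and every threshold.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    effective_tests,
    joint_inversion_regression,
    preresidualize,
    rank_int,
    significance_tiers,
)
from .generalization import generalize
from .genotyper import call_cohort, build_reference
from .simulate import SimulationConfig, simulate_cohort, simulate_phenotypes, simulate_two_cohorts

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds, and options for one pipeline run.

    With no genotype path the pipeline generates its own cohort from
    ``sim`` (the bundled synthetic-data generator).
    """

    output_dir: str = "results"
    genotypes_vcf: str | None = None
    reference_vcf: str | None = None
    orientation_tsv: str | None = None
    reference_model_json: str | None = None
    phenotypes_tsv: str | None = None
    covariates_tsv: str | None = None
    tag_rules_tsv: str | None = None
    min_snps: int = 15
    min_diff: float = 0.1
    max_ind_missing: float = 0.10
    max_snp_missing: float = 0.05
    hwe_p: float = 1e-6
    min_maf: float = 0.01
    relatedness_threshold: float = 0.1
    alpha: float = 0.05
    gw_alpha: float = 5e-8
    seed: int = 0
    adjust_global: bool = False
    generalize: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.min_diff < 1:
            raise ValueError("min_diff must be in (0, 1)")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        for name in ("max_ind_missing", "max_snp_missing", "min_maf", "alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        """Load a run configuration from a flat YAML key-value file.

        Keys starting with ``sim_`` set the corresponding field of the
        embedded SimulationConfig; everything else maps to RunConfig
        fields. Unknown keys are an error.
        """
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        run_fields = {f.name for f in dataclasses.fields(cls)}
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        run_kwargs, sim_kwargs = {}, {}
        for key, value in doc.items():
            if key.startswith("sim_") and key[4:] in sim_fields:
                sim_kwargs[key[4:]] = value
            elif key in run_fields:
                run_kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r} in {path}")
        return cls(sim=SimulationConfig(**sim_kwargs), **run_kwargs)


def calls_to_frame(calls: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "inversion_id": c.inversion_id,
                "H_NN": c.scores["NN"],
                "H_NI": c.scores["NI"],
                "H_II": c.scores["II"],
                "genotype": c.called_genotype,
                "dosage": -1 if c.dosage is None else c.dosage,
                "n_snps": c.n_snps_used,
                "score_diff": c.score_diff,
                "qc_pass": c.qc_pass,
                "flag_min_snps": c.qc_flags.get("min_snps", False),
                "flag_min_diff": c.qc_flags.get("min_diff", False),
                "flag_tie": c.qc_flags.get("tie", False),
            }
            for c in calls
        ]
    )


def association_to_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "inversion_id": r.inversion_id,
                "phenotype_id": r.phenotype_id,
                "coding": r.coding,
                "beta": r.beta,
                "se": r.se,
                "t": r.t,
                "p": r.p,
                "incremental_r2": r.incremental_r2,
                "n": r.n,
                "tier": r.tier,
            }
            for r in results
        ]
    )


def associate_cohort(
    dosage_df: pd.DataFrame,
    pheno,
    config: RunConfig,
    adjust_global: bool | None = None,
) -> tuple[list, "object"]:
    """Residualize -> INT -> joint regression -> multiplicity tiers."""
    adjust = config.adjust_global if adjust_global is None else adjust_global
    resid = preresidualize(pheno, adjust_global=adjust)
    transformed = pd.DataFrame(
        {c: rank_int(resid[c].to_numpy()) for c in resid.columns}, index=resid.index
    )
    results = joint_inversion_regression(transformed, dosage_df.loc[transformed.index])
    corr = transformed.corr().to_numpy()
    mult = effective_tests(corr, alpha=config.alpha)
    for r in results:
        r.tier = significance_tiers(r.p, mult, gw_alpha=config.gw_alpha)
    return results, mult


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the results bundle.

    Returns a dict of output paths.  Stage failures raise PipelineError
    naming the stage; no partial file from a failed stage is left behind.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("invassoc")
    root.addHandler(handler)
    root.setLevel(config.verbosity)
    paths: dict = {"log": str(log_path)}
    try:
        logger.info("invassoc %s", __version__)
        logger.info("seed=%d", config.seed)
        for f in dataclasses.fields(RunConfig):
            if f.name not in ("sim",):
                logger.info("config %s=%r", f.name, getattr(config, f.name))

        # --- simulate ---------------------------------------------------
        try:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            cohort = simulate_cohort(sim)
            pheno = simulate_phenotypes(cohort.truth, sim, sex=cohort.sex)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("simulate", str(e)) from e

        # --- build reference and call ------------------------------------
        all_calls = []
        dosage_cols = {}
        try:
            for inv_id, samples in cohort.genotypes.items():
                ref = build_reference(cohort.panels[inv_id], inv_id)
                calls, callability = call_cohort(
                    samples, ref, min_snps=config.min_snps, min_diff=config.min_diff
                )
                logger.info("inversion %s callability=%.4f", inv_id, callability)
                all_calls.extend(calls)
                dosage_cols[inv_id] = pd.Series(
                    [c.dosage if c.qc_pass else np.nan for c in calls],
                    index=[c.sample_id for c in calls],
                )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("call", str(e)) from e
        calls_path = out / "calls.tsv"
        calls_to_frame(all_calls).to_csv(calls_path, sep="\t", index=False)
        paths["calls"] = str(calls_path)

        # --- associate ----------------------------------------------------
        try:
            dosage_df = pd.DataFrame(dosage_cols).dropna()
            if dosage_df.empty or (dosage_df.nunique() <= 1).any():
                raise ValueError("no callable inversion with variable dosage")
            keep = dosage_df.index
            pheno_sub = dataclasses.replace(
                pheno,
                phenotypes=pheno.phenotypes.loc[keep],
                covariates=pheno.covariates.loc[keep],
                global_measures=pheno.global_measures.loc[keep],
            )
            results, mult = associate_cohort(dosage_df, pheno_sub, config)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("associate", str(e)) from e
        assoc_path = out / "association.tsv"
        association_to_frame(results).to_csv(assoc_path, sep="\t", index=False)
        paths["association"] = str(assoc_path)
        mult_path = out / "multiplicity.json"
        mult_path.write_text(
            json.dumps(
                {
                    "t_e": mult.t_e,
                    "eigenvalues": list(mult.eigenvalues),
                    "alpha": mult.alpha,
                    "bonferroni_threshold": mult.bonferroni_threshold,
                }
            )
        )
        paths["multiplicity"] = str(mult_path)

        # --- generalize (optional) ---------------------------------------
        if config.generalize:
            try:
                (c_d, p_d), (c_r, p_r), _, _ = simulate_two_cohorts(sim, beta_corr=0.8)
                res_d, _ = associate_cohort(c_d.truth.astype(float), p_d, config)
                res_r, _ = associate_cohort(c_r.truth.astype(float), p_r, config)
                g = generalize(association_to_frame(res_d), association_to_frame(res_r))
            except Exception as e:  # noqa: BLE001
                raise PipelineError("generalize", str(e)) from e
            gen_path = out / "generalization.json"
            gen_path.write_text(json.dumps(dataclasses.asdict(g), default=float))
            paths["generalization"] = str(gen_path)

        logger.info("pipeline complete: %s", sorted(paths))
        return paths
    finally:
        root.removeHandler(handler)
        handler.close()
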