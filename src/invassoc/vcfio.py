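"""Readers and writers for VCF cohorts, phased panels, and model JSON.

Study cohorts travel as VCF with GT plus a GP (genotype probability)
FORMAT field holding the per-genotype posterior; reference panels as
phased VCF plus a tab-separated orientation table mapping each haplotype
(sample, haplotype index) to I or NI.  Reference models round-trip
through a versioned JSON document.  Reading uses cyvcf2; coordinates are
1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotyper import GROUPS, ReferenceModel, SampleGenotypes
from .simulate import HaplotypePanel

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "write_cohort_vcf",
    "read_genotype_region",
    "write_reference_panel",
    "read_reference_panel",
    "serialize_reference_model",
    "deserialize_reference_model",
    "write_phenotypes_tsv",
    "write_tag_rules_tsv",
    "read_tag_rules_tsv",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior probabilities">
"""


def _gt_string(dosage: int, phased: bool = False) -> str:
    sep = "|" if phased else "/"
    return {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}[dosage]


def write_cohort_vcf(samples: list, snp_meta: pd.DataFrame, path: str) -> None:
    """Write a cohort of SampleGenotypes as a VCF with GT and GP fields."""
    ids = [s.sample_id for s in samples]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("##contig=<ID=%s>\n" % snp_meta["chrom"].iloc[0])
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        for i, row in snp_meta.reset_index(drop=True).iterrows():
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                row["id"],
                row["ref"],
                row["alt"],
                ".",
                "PASS",
                ".",
                "GT:GP",
            ]
            for s in samples:
                if s.missing[i]:
                    fields.append("./.:.")
                else:
                    post = s.posteriors[i]
                    gt = _gt_string(int(np.argmax(post)))
                    gp = ",".join(f"{x:.6f}" for x in post)
                    fields.append(f"{gt}:{gp}")
            fh.write("\t".join(fields) + "\n")


def _parse_region(region: str | None):
    if region is None:
        return None
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, None, None
    start, _, end = span.partition("-")
    return chrom, int(start), int(end)


def read_genotype_region(vcf_path: str, region: str | None = None) -> list:
    """Read per-sample genotype posteriors from a VCF region.

    Uses the GP field when present, else point masses on the hard GT
    call; half-calls and missing genotypes are masked; multi-allelic
    sites are skipped with a warning.  ``region`` is chrom:start-end,
    1-based inclusive, or None for the whole file.
    """
    vcf = VCF(vcf_path)
    sample_ids = vcf.samples
    parsed = _parse_region(region)
    snp_ids, posts, miss = [], [], []
    n_records = 0
    for variant in vcf:
        n_records += 1
        if parsed is not None:
            chrom, start, end = parsed
            if variant.CHROM != chrom:
                continue
            if start is not None and not (start <= variant.POS <= end):
                continue
        if len(variant.ALT) != 1:
            logger.warning("skipping multi-allelic site %s", variant.ID or variant.POS)
            continue
        n = len(sample_ids)
        post = np.full((n, 3), np.nan)
        missing = np.zeros(n, dtype=bool)
        try:
            gp = variant.format("GP")
        except KeyError:
            gp = None
        gts = variant.genotypes
        for j in range(n):
            a0, a1 = gts[j][0], gts[j][1]
            if a0 < 0 or a1 < 0:
                missing[j] = True
                continue
            if gp is not None and np.isfinite(gp[j]).all() and gp[j].sum() > 0:
                post[j] = gp[j] / gp[j].sum()
            else:
                post[j] = 0.0
                post[j][a0 + a1] = 1.0
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        posts.append(post)
        miss.append(missing)
    if not snp_ids:
        raise ValueError(f"no usable records in region {region!r} of {vcf_path}")
    post_arr = np.stack(posts, axis=1)  # (n_samples, L, 3)
    miss_arr = np.stack(miss, axis=1)
    post_arr = np.where(miss_arr[:, :, None], 1.0 / 3.0, post_arr)
    return [
        SampleGenotypes(
            sample_id=sid,
            snp_ids=list(snp_ids),
            posteriors=post_arr[j],
            missing=miss_arr[j],
        )
        for j, sid in enumerate(sample_ids)
    ]


def write_reference_panel(panel: HaplotypePanel, vcf_path: str, tsv_path: str) -> None:
    """Write a panel as phased VCF plus a haplotype-orientation TSV."""
    n_ind = panel.n_individuals
    ids = [f"REF{j:04d}" for j in range(n_ind)]
    H = panel.haplotypes
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("##contig=<ID=%s>\n" % panel.snp_meta["chrom"].iloc[0])
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        for i, row in panel.snp_meta.reset_index(drop=True).iterrows():
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                row["id"],
                row["ref"],
                row["alt"],
                ".",
                "PASS",
                ".",
                "GT",
            ]
            for j in range(n_ind):
                h0, h1 = panel.diploid_pairing[j]
                fields.append(f"{H[h0, i]}|{H[h1, i]}")
            fh.write("\t".join(fields) + "\n")
    rows = []
    for j in range(n_ind):
        for hap_idx in (0, 1):
            rows.append(
                {
                    "sample": ids[j],
                    "haplotype": hap_idx,
                    "orientation": panel.orientation[panel.diploid_pairing[j, hap_idx]],
                }
            )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_reference_panel(
    vcf_path: str, orientation_tsv: str, inversion_id: str = "inv"
) -> HaplotypePanel:
    """Read a phased VCF and orientation TSV into a HaplotypePanel."""
    orient_df = pd.read_csv(orientation_tsv, sep="\t", dtype={"haplotype": int})
    orient_map = {
        (r["sample"], r["haplotype"]): r["orientation"] for _, r in orient_df.iterrows()
    }
    vcf = VCF(vcf_path)
    sample_ids = vcf.samples
    meta_rows, hap_cols = [], []
    for variant in vcf:
        gts = variant.genotypes
        col = np.empty(2 * len(sample_ids), dtype=np.int8)
        for j, gt in enumerate(gts):
            if len(gt) < 3 or not gt[2]:
                raise ValueError(
                    f"unphased genotype for sample {sample_ids[j]} at record "
                    f"{variant.ID or variant.POS}"
                )
            col[2 * j], col[2 * j + 1] = gt[0], gt[1]
        hap_cols.append(col)
        meta_rows.append(
            {
                "id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "ref": variant.REF,
                "alt": variant.ALT[0],
            }
        )
    haplotypes = np.column_stack(hap_cols)
    orientation = []
    for j, sid in enumerate(sample_ids):
        for hap_idx in (0, 1):
            key = (sid, hap_idx)
            if key not in orient_map:
                raise ValueError(f"orientation missing for haplotype {key}")
            orientation.append(orient_map[key])
    pairing = np.arange(2 * len(sample_ids)).reshape(len(sample_ids), 2)
    return HaplotypePanel(
        snp_meta=pd.DataFrame(meta_rows),
        haplotypes=haplotypes,
        orientation=np.array(orientation),
        diploid_pairing=pairing,
        inversion_id=inversion_id,
    )


def serialize_reference_model(model: ReferenceModel) -> str:
    """Lossless JSON serialization of a reference model."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "inversion_id": model.inversion_id,
        "snp_meta": model.snp_meta.to_dict(orient="list"),
        "genotype_freqs": model.genotype_freqs.tolist(),
        "weights": model.weights.tolist(),
        "group_counts": {g: int(model.group_counts.get(g, 0)) for g in GROUPS},
        "uniform_groups": list(model.uniform_groups),
    }
    return json.dumps(doc)


def deserialize_reference_model(text: str) -> ReferenceModel:
    doc = json.loads(text)  # malformed JSON raises, never silent defaults
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"reference-model schema version {version!r} != supported {SCHEMA_VERSION}"
        )
    return ReferenceModel(
        inversion_id=doc["inversion_id"],
        snp_meta=pd.DataFrame(doc["snp_meta"]),
        genotype_freqs=np.asarray(doc["genotype_freqs"], dtype=float),
        weights=np.asarray(doc["weights"], dtype=float),
        group_counts=doc["group_counts"],
        uniform_groups=tuple(doc.get("uniform_groups", ())),
    )


def write_phenotypes_tsv(pheno, pheno_path: str, covar_path: str) -> None:
    df = pheno.phenotypes.join(pheno.global_measures)
    df.to_csv(pheno_path, sep="\t", index_label="sample")
    pheno.covariates.to_csv(covar_path, sep="\t", index_label="sample")


def write_tag_rules_tsv(rules: list, path: str) -> None:
    pd.DataFrame(
        [
            {
                "inversion_id": r.inversion_id,
                "snp_id": r.snp_id,
                "inverted_allele": r.inverted_allele,
                "alt_allele": r.alt_allele,
                "r2": r.r2,
                "min_r2": r.min_r2,
            }
            for r in rules
        ]
    ).to_csv(path, sep="\t", index=False)


def read_tag_rules_tsv(path: str) -> list:
    from .genotyper import TagSNPRule

    df = pd.read_csv(path, sep="\t")
    return [
        TagSNPRule(
            inversion_id=r["inversion_id"],
            snp_id=r["snp_id"],
            inverted_allele=str(r["inverted_allele"]),
            alt_allele=str(r["alt_allele"]),
            r2=float(r.get("r2", 1.0)),
            min_r2=float(r.get("min_r2", 0.9)),
        )
        for _, r in df.iterrows()
    ]
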