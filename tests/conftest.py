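import numpy as np
import pandas as pd
import pytest

from invassoc.genotyper import SampleGenotypes
from invassoc.simulate import HaplotypePanel, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def clean_config():
    """Error-free, fully certain genotypes with strong family divergence."""
    return SimulationConfig(
        seed=11,
        n_study=2000,
        n_snps=30,
        divergence=0.49,
        genotype_error_rate=0.0,
        certainty_model=("constant", 1.0),
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    return simulate_cohort(clean_config)


def hand_panel():
    """6 individuals (3 NN, 2 NI, 1 II), 3 SNPs, fully specified by hand.

    Haplotype rows are (individual, chromosome) in order; SNP0 is a
    perfect tag (alt on every I haplotype, ref on every NI), SNP1 is
    uninformative (alt everywhere), SNP2 is a partial tag.
    """
    haplotypes = np.array(
        [
            # ind0 NN        ind1 NN       ind2 NN
            [0, 1, 0], [0, 1, 1],
            [0, 1, 0], [0, 1, 0],
            [0, 1, 1], [0, 1, 1],
            # ind3 NI        ind4 NI
            [0, 1, 0], [1, 1, 1],
            [1, 1, 1], [0, 1, 0],
            # ind5 II
            [1, 1, 1], [1, 1, 0],
        ]
    )
    orientation = np.array(
        ["NI", "NI", "NI", "NI", "NI", "NI", "NI", "I", "I", "NI", "I", "I"]
    )
    meta = pd.DataFrame(
        {
            "id": ["s0", "s1", "s2"],
            "chrom": "1",
            "pos": [100, 200, 300],
            "ref": "A",
            "alt": "G",
        }
    )
    pairing = np.arange(12).reshape(6, 2)
    return HaplotypePanel(
        snp_meta=meta,
        haplotypes=haplotypes,
        orientation=orientation,
        diploid_pairing=pairing,
        inversion_id="hand",
    )


def make_sample(posteriors, sample_id="s", snp_ids=None, missing=None):
    P = np.asarray(posteriors, dtype=float)
    L = P.shape[0]
    return SampleGenotypes(
        sample_id=sample_id,
        snp_ids=snp_ids or [f"s{i}" for i in range(L)],
        posteriors=P,
        missing=np.zeros(L, dtype=bool) if missing is None else np.asarray(missing, bool),
    )
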