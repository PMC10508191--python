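#!/usr/bin/env python
"""Does a region tag SNP explain the inversion-phenotype signal?

Mirrors the conditional-and-joint analysis: offer the stepwise
selection a SNP in near-perfect LD with the inversion and refit the
inversion association with the selected SNPs as covariates.  When the
phenotype signal is generated through the inversion, the tag SNP
absorbs it; an independent SNP effect leaves the inversion beta intact.
Writes results/conditional.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from invassoc.association import conditional_adjustment, joint_inversion_regression
from invassoc.studies import absorption_study, simulate_hwe_dosages

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    out = absorption_study(n_replicates=25, n=5000, beta=0.3, seed=2023)
    rows = [
        {"scenario": "signal_through_inversion",
         "median_unconditional_p": out["median_unconditional_p"],
         "median_conditional_p": out["median_conditional_p"],
         "mean_tag_r2": out["mean_tag_r2"]}
    ]
    print("signal generated through the inversion, tag SNP offered "
          f"(mean r2 {out['mean_tag_r2']:.3f}):")
    print(f"  median p unconditional {out['median_unconditional_p']:.2e} "
          f"-> conditional {out['median_conditional_p']:.3f} (signal absorbed)")

    # control: an independent SNP effect must not disturb the inversion
    rng = np.random.default_rng(2024)
    n = 5000
    d = simulate_hwe_dosages(rng, n, 1)[:, 0]
    snp = simulate_hwe_dosages(rng, n, 1, q=0.3)[:, 0]
    y = 0.2 * d + 0.3 * snp + rng.standard_normal(n)
    selected, cond = conditional_adjustment(y, d, pd.DataFrame({"snp": snp}))
    uncond = joint_inversion_regression(
        pd.DataFrame({"y": y}), pd.DataFrame({"d": d})
    )[0]
    rows.append(
        {"scenario": "independent_snp_effect",
         "median_unconditional_p": uncond.p,
         "median_conditional_p": cond.p,
         "mean_tag_r2": np.corrcoef(d, snp)[0, 1] ** 2}
    )
    print(f"independent SNP (selected: {selected}): inversion beta "
          f"{uncond.beta:.3f} -> {cond.beta:.3f} after conditioning "
          "(effect retained)")
    pd.DataFrame(rows).to_csv(OUT / "conditional.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
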