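#!/usr/bin/env python
"""QC and LD pruning of the simulated cohort.

Applies the standard filter stack (SNP/individual missingness, MAF,
relatedness) and the r^2 > 0.4 sliding-window pruner (200-SNP windows,
25-SNP steps) used for the allele-frequency analyses.
"""

from pathlib import Path

import pandas as pd

from finepop import genio

DEMO = Path("results/analysis/demo")
OUT = Path("results/analysis")


def main() -> None:
    G = genio.read_plink(str(DEMO / "demo"))
    G, qc_report = genio.qc_filter(G, genio.QCThresholds())
    G, rel_report = genio.relatedness_filter(G, cutoff=0.25)
    keep = genio.ld_prune(G, r2_max=0.4, window_snps=200, step_snps=25)
    qc_report.to_csv(OUT / "qc_removals.tsv", sep="\t", index=False)
    pd.DataFrame({"id": keep}).to_csv(OUT / "pruned_keep.tsv", sep="\t", index=False)
    print(f"after QC: {G.n_ind} individuals x {G.n_snp} SNPs "
          f"({len(qc_report)} removals, {len(rel_report)} related pairs)")
    print(f"LD pruning keeps {len(keep)}/{G.n_snp} SNPs")


if __name__ == "__main__":
    main()
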