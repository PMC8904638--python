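#!/usr/bin/env python
"""Population structure of the simulated cohort: FST, PCA, RoH.

Pairwise Weir-Cockerham FST separates the three sources; PCA places the
admixed groups between their sources; the RoH scan summarizes per-group
homozygosity.
"""

from pathlib import Path

import pandas as pd

from finepop import genio, popstats

DEMO = Path("results/analysis/demo")
OUT = Path("results/analysis")


def main() -> None:
    G = genio.read_plink(str(DEMO / "demo"))
    keep = pd.read_csv(OUT / "pruned_keep.tsv", sep="\t")["id"]
    G = G.take_snps(G.snp_meta["id"].isin(keep).to_numpy())

    fst, flagged = popstats.pairwise_fst_matrix(G)
    fst.to_csv(OUT / "fst_matrix.tsv", sep="\t", float_format="%.5g")
    print("pairwise FST (sources vs sources should be largest):")
    print(fst.round(4).to_string())

    scores, frac = popstats.pca_genotypes(G, n_components=4)
    pca = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    pca.insert(0, "id", G.sample_meta["id"])
    pca.insert(1, "population", G.sample_meta["population"])
    pca.to_csv(OUT / "pca_scores.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"PCA variance fractions: {frac.round(3)}")

    segs = popstats.detect_roh(G, window_snps=100, min_kb=1000)
    per_ind, per_group = popstats.roh_summary(segs, G.sample_meta)
    per_group.to_csv(OUT / "roh_group_means.tsv", sep="\t", index=False)
    print("RoH per-group means:")
    print(per_group.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
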