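#!/usr/bin/env python
"""Haplotype painting, clustering, and TVD heterogeneity.

Paints every individual against all others (Li-Stephens Viterbi), builds
copying vectors, clusters them by TVD agglomeration, applies the size and
TVD-pooling refinements, and reports the three-level TVD heterogeneity of
the admixed ("focal") individuals.
"""

from pathlib import Path

import pandas as pd

from finepop import finestructure as fs
from finepop import genio, painter, simdata

DEMO = Path("results/analysis/demo")
OUT = Path("results/analysis")


def main() -> None:
    G = genio.read_eigenstrat(str(DEMO / "demo"))
    panel = rebuild_panel(G)
    M = painter.paint_all_vs_all(panel, painter.PainterConfig())
    M.chunk_counts.to_csv(OUT / "chunkcounts.tsv", sep="\t", float_format="%.6g")
    vecs = painter.copying_vectors(M, {i: i for i in M.ids}, basis="counts")
    tree, assign = fs.build_tree(vecs, n_clusters=10)
    # TVD pooling on the cluster-aggregated donor basis; at this cohort
    # scale fragment-vs-fragment TVDs sit near 0.1, so the pooling
    # threshold is set accordingly (the 0.035 default targets much larger
    # cohorts where copying vectors are far less noisy)
    vecs_cluster = painter.copying_vectors(M, assign.of, basis="counts")
    assign = fs.refine_tree_tvd(assign, vecs_cluster, threshold=0.2, max_pool=6)
    assign = fs.refine_tree_size(tree, assign, min_cluster_individuals=3)
    assign.to_frame().to_csv(OUT / "clusters.tsv", sep="\t", index=False)
    pops = G.sample_meta.set_index("id")["population"]
    cross = pd.crosstab(pops[assign.to_frame()["id"]].to_numpy(),
                        assign.to_frame()["cluster"])
    print("cluster composition (rows = true groups):")
    print(cross.to_string())

    focal = G.sample_meta.loc[
        G.sample_meta["population"].str.startswith("KW"), "id"
    ].tolist()
    reports = fs.tvd_levels({"counts": vecs}, assign, focal)
    long = pd.concat([r.to_frame() for r in reports], ignore_index=True)
    long.to_csv(OUT / "tvd_levels.tsv", sep="\t", index=False, float_format="%.6g")
    med = long.groupby("level")["tvd"].median()
    print("\nmedian TVD by level:")
    print(med.round(4).to_string())


def rebuild_panel(G):
    """Demo genotypes were written from phased haplotypes; re-simulating
    with the same seed restores phase (written panels keep genotypes only)."""
    from finepop import pipeline

    demo = pipeline.make_demo(1, "scratch/demo_rebuild", n_snps=3000,
                              n_per_pop=25, n_admixed=30)
    return demo["panel"]


if __name__ == "__main__":
    main()
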