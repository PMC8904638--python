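#!/usr/bin/env python
"""Admixture dating from weighted-LD decay, and date comparisons.

Recovers the pulse times of the recently admixed (13 generations) and
older (19 generations) groups from replicate weighted-LD fits, then
contrasts the two per-replicate date distributions with a Bonferroni-
corrected Wilcoxon rank-sum test — the recent group must date younger.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from finepop import dating, scenarios

OUT = Path("results/analysis")


def main(seed: int = 1) -> None:
    rows = []
    dates = {}
    for label, g_true in (("recent", 13), ("older", 19)):
        out = scenarios.date_recovery(
            g_true, n_reps=5, seed=seed + g_true,
            n_snps=6000, n_per_pop=60, n_admixed=100,
        )
        dates[label] = out["estimates"][np.isfinite(out["estimates"])]
        rows.append({"group": label, "true_g": g_true,
                     "median_ghat": out["median"], "n_converged": out["n_converged"]})
        print(f"{label}: true {g_true} generations, "
              f"median estimate {out['median']:.1f} over {out['n_converged']} fits")
    pd.DataFrame(rows).to_csv(OUT / "dates.tsv", sep="\t", index=False,
                              float_format="%.4g")
    cmp = dating.compare_date_distributions(dates)
    cmp.to_csv(OUT / "date_comparison.tsv", sep="\t", index=False, float_format="%.4g")
    print("\nWilcoxon rank-sum comparison of per-replicate dates:")
    print(cmp.round(5).to_string(index=False))


if __name__ == "__main__":
    main()
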