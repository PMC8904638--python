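"""Allele-frequency population statistics: Weir-Cockerham FST, runs of
homozygosity, and PCA on genotypes or coancestry matrices.

FST follows the Weir & Cockerham (1984) variance-component estimator for
r = 2 populations, combining SNPs as a ratio of sums, FST = sum(a) /
sum(a + b + c), where a is the among-population, b the among-individual
(within population) and c the within-individual component.  Negative
estimates are reported as computed (a ``clip`` flag exists for display).

The RoH scanner mirrors the PLINK sliding-window approach: windows of
``window_snps`` consecutive SNPs slide one SNP at a time; a window is a hit
when it contains at most ``max_het`` heterozygous and ``max_missing``
missing calls; a SNP is in the homozygous state when the fraction of
windows covering it that are hits reaches ``hit_fraction``; maximal runs of
such SNPs are emitted if they span at least ``min_kb`` kb and
``min_seg_snps`` SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix


@dataclass
class FstResult:
    fst: float
    sum_a: float
    sum_abc: float
    n_snps_used: int


@dataclass
class RoHSegment:
    individual: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


def _pop_mask(G: GenotypeMatrix, pop) -> np.ndarray:
    if isinstance(pop, str):
        mask = (G.sample_meta["population"] == pop).to_numpy()
    else:
        mask = np.asarray(pop)
        if mask.dtype != bool:
            mask = np.isin(np.arange(G.n_ind), mask)
    if not mask.any():
        raise ValueError(f"empty population {pop!r}")
    return mask


def wc_components(G: GenotypeMatrix, popA, popB) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Weir-Cockerham components (a, b, c) and a usability mask."""
    maskA = _pop_mask(G, popA)
    maskB = _pop_mask(G, popB)
    if maskA.sum() < 2 or maskB.sum() < 2:
        raise ValueError("each population needs >= 2 individuals")
    r = 2
    comps = []
    for mask in (maskA, maskB):
        calls = G.calls[mask]
        ok = calls != MISSING
        n_i = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(ok, calls, 0).sum(axis=0) / (2 * np.where(n_i > 0, n_i, 1))
            h_i = ((calls == 1) & ok).sum(axis=0) / np.where(n_i > 0, n_i, 1)
        comps.append((n_i, p_i, h_i))
    (nA, pA, hA), (nB, pB, hB) = comps
    usable = (nA >= 1) & (nB >= 1)
    n_bar = (nA + nB) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (nA**2 + nB**2) / (r * n_bar)) / (r - 1)
        p_bar = (nA * pA + nB * pB) / (r * n_bar)
        s2 = (nA * (pA - p_bar) ** 2 + nB * (pB - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (nA * hA + nB * hB) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0
    poly = (p_bar > 0) & (p_bar < 1)
    usable &= poly & (n_bar > 1) & np.isfinite(a + b + c)
    usable &= np.where(usable, (a + b + c) != 0, False)
    return a, b, c, usable


def wc_fst(G: GenotypeMatrix, popA, popB) -> FstResult:
    """Weir-Cockerham FST between two populations (ratio of sums)."""
    a, b, c, usable = wc_components(G, popA, popB)
    if not usable.any():
        raise ValueError("no usable SNPs: all monomorphic or degenerate")
    sum_a = float(a[usable].sum())
    sum_abc = float((a + b + c)[usable].sum())
    return FstResult(fst=sum_a / sum_abc, sum_a=sum_a, sum_abc=sum_abc, n_snps_used=int(usable.sum()))


def pairwise_fst_matrix(
    G: GenotypeMatrix, grouping: str = "population", clip: bool = False
) -> tuple[pd.DataFrame, list[str]]:
    """Symmetric FST matrix over groups; returns (matrix, flagged groups).

    Groups with fewer than 2 individuals are flagged and their rows filled
    with NaN rather than silently dropped.
    """
    labels = G.sample_meta[grouping]
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = labels.value_counts()
    flagged = [g for g in groups if sizes[g] < 2]
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            if gi in flagged or gj in flagged:
                val = np.nan
            else:
                val = wc_fst(
                    G, (labels == gi).to_numpy(), (labels == gj).to_numpy()
                ).fst
                if clip:
                    val = max(val, 0.0)
            mat.loc[gi, gj] = mat.loc[gj, gi] = val
    return mat, flagged


# ---------------------------------------------------------------------------
# runs of homozygosity


def detect_roh(
    G: GenotypeMatrix,
    window_snps: int = 100,
    max_het: int = 1,
    max_missing: int = 5,
    min_kb: float = 1000.0,
    hit_fraction: float = 0.05,
    min_seg_snps: int = 100,
) -> list[RoHSegment]:
    """Sliding-window RoH scan per individual and chromosome."""
    segments: list[RoHSegment] = []
    ids = G.sample_meta["id"].to_numpy()
    for chrom in G.snp_meta["chrom"].unique():
        cidx = np.flatnonzero((G.snp_meta["chrom"] == chrom).to_numpy())
        m = len(cidx)
        if m < window_snps:
            warnings.warn(f"chrom {chrom}: {m} SNPs < window of {window_snps}; skipped")
            continue
        bp = G.snp_meta["bp"].to_numpy()[cidx]
        n_win = m - window_snps + 1
        # windows covering SNP t: starts in [max(0, t-w+1), min(t, n_win-1)]
        t = np.arange(m)
        lo = np.maximum(0, t - window_snps + 1)
        hi = np.minimum(t, n_win - 1)
        cover = (hi - lo + 1).astype(float)
        for i in range(G.n_ind):
            calls = G.calls[i, cidx]
            het = (calls == 1).astype(np.int64)
            mis = (calls == MISSING).astype(np.int64)
            ch = np.concatenate([[0], np.cumsum(het)])
            cm_ = np.concatenate([[0], np.cumsum(mis)])
            starts = np.arange(n_win)
            whet = ch[starts + window_snps] - ch[starts]
            wmis = cm_[starts + window_snps] - cm_[starts]
            hit = ((whet <= max_het) & (wmis <= max_missing)).astype(np.int64)
            chit = np.concatenate([[0], np.cumsum(hit)])
            n_hits = chit[hi + 1] - chit[lo]
            score = n_hits / cover
            in_state = score >= hit_fraction
            # maximal runs
            j = 0
            while j < m:
                if in_state[j]:
                    k = j
                    while k + 1 < m and in_state[k + 1]:
                        k += 1
                    n_seg = k - j + 1
                    kb = (bp[k] - bp[j] + 1) / 1000.0
                    if kb >= min_kb and n_seg >= min_seg_snps:
                        segments.append(
                            RoHSegment(
                                individual=str(ids[i]),
                                chrom=str(chrom),
                                start_bp=int(bp[j]),
                                end_bp=int(bp[k]),
                                n_snps=n_seg,
                            )
                        )
                    j = k + 1
                else:
                    j += 1
    return segments


def roh_summary(
    segments: list[RoHSegment], sample_meta: pd.DataFrame, grouping: str = "population"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual (count, total kb) and per-group means.

    Individuals with no segments contribute (0, 0).
    """
    per_ind = pd.DataFrame(
        {"id": sample_meta["id"], "group": sample_meta[grouping], "n_segments": 0, "total_kb": 0.0}
    ).set_index("id")
    for seg in segments:
        per_ind.loc[seg.individual, "n_segments"] += 1
        per_ind.loc[seg.individual, "total_kb"] += seg.length_kb
    per_group = per_ind.groupby("group")[["n_segments", "total_kb"]].mean()
    per_group.columns = ["mean_n_segments", "mean_total_kb"]
    return per_ind.reset_index(), per_group.reset_index()


def segments_to_frame(segments: list[RoHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.chrom, s.start_bp, s.end_bp, s.individual, s.n_snps, s.length_kb)
            for s in segments
        ],
        columns=["chrom", "start_bp", "end_bp", "id", "n_snps", "length_kb"],
    )


# ---------------------------------------------------------------------------
# PCA


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|score| entry of each
    component is made positive."""
    out = scores.copy()
    for k in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, k])))
        if out[j, k] < 0:
            out[:, k] = -out[:, k]
    return out


def pca_genotypes(G: GenotypeMatrix, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA with per-SNP centering and sqrt(p(1-p)) scaling.

    Missing dosages become 0 after centering (mean imputation).  Returns
    (scores of shape n_ind x k, fraction of variance per component).
    """
    d = G.dosage()
    ok = ~np.isnan(d)
    if not ok.any(axis=0).all():
        raise ValueError("all-missing SNP present; run QC first")
    mean = np.nansum(d, axis=0) / ok.sum(axis=0)
    p = mean / 2.0
    scale = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
    X = (d - mean[None, :]) / scale[None, :]
    X[~ok] = 0.0
    # drop invariant SNPs (p==0 or 1): their column is all zero anyway
    X[:, (p <= 0) | (p >= 1)] = 0.0
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if n_components > rank:
        warnings.warn(f"n_components={n_components} > rank {rank}; truncated")
        n_components = rank
    var = s**2
    frac = var[:n_components] / var.sum()
    scores = u[:, :n_components] * s[:n_components]
    return _fix_signs(scores), frac


def pca_coancestry(M: np.ndarray | pd.DataFrame, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """PCA of a (square) coancestry matrix: rows are observations, columns
    variables; columns centered, unscaled."""
    A = np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("coancestry matrix must be square")
    X = A - A.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > max(s[0], 1e-300) * 1e-12).sum()) if len(s) and s[0] > 0 else 0
    if n_components > rank:
        if rank < n_components:
            warnings.warn(f"n_components={n_components} > rank {rank}; truncated")
        n_components = rank
    var = s**2
    total = var.sum()
    frac = var[:n_components] / total if total > 0 else np.zeros(n_components)
    scores = u[:, :n_components] * s[:n_components]
    return _fix_signs(scores), frac
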