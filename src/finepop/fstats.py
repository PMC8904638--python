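"""Patterson f-statistics with weighted block-jackknife standard errors.

Implements admixture f3, outgroup f3, f4, and the f4-ratio on population
allele-frequency tables.  Per-SNP terms:

    f3(C; A, B) = (c - a)(c - b) - hc_correction        (admixture test)
    f4(A, B; C, D) = (a - b)(c - d)

where a, b, c, d are sample frequencies of the counted allele.  The f3
bias-correction term c_hat(1 - c_hat)/(n_C - 1) (n_C = non-missing
chromosomes in the target) makes the estimator unbiased under binomial
sampling of the target; it is toggleable so that exact population-frequency
examples can be checked without it.  A significantly negative f3
(Z < -3) is evidence that the target is admixed between sources related to
A and B.

Standard errors come from a delete-one-block jackknife over contiguous
genomic blocks (default 5 cM), with unequal block sizes handled by the
weighted jackknife of Busing, Meijer & van der Leeden (1999).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix


@dataclass
class AlleleFreqTable:
    """Sample allele frequencies per population x SNP.

    ``freqs[pop]`` and ``n_chrom[pop]`` are aligned to ``snp_meta`` rows;
    ``n_chrom`` counts non-missing chromosomes (0 marks a population with
    no data at that SNP).
    """

    freqs: dict[str, np.ndarray]
    n_chrom: dict[str, np.ndarray]
    snp_meta: pd.DataFrame

    @property
    def n_snp(self) -> int:
        return len(self.snp_meta)

    def require(self, pops: list[str]) -> np.ndarray:
        """Mask of SNPs with data in every requested population."""
        for p in pops:
            if p not in self.freqs:
                raise KeyError(f"unknown population {p!r}")
        mask = np.ones(self.n_snp, dtype=bool)
        for p in pops:
            mask &= self.n_chrom[p] > 0
        return mask


@dataclass
class FStatResult:
    name: str
    pops: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_snps: int
    flags: list[str] = field(default_factory=list)


def allele_freqs(G: GenotypeMatrix, grouping: str = "population") -> AlleleFreqTable:
    """Sample frequency of the counted allele and chromosome counts per group."""
    labels = G.sample_meta[grouping]
    freqs, n_chrom = {}, {}
    for g in dict.fromkeys(labels):
        mask = (labels == g).to_numpy()
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        calls = G.calls[mask]
        ok = calls != MISSING
        nc = 2 * ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(ok, calls, 0).sum(axis=0) / np.where(nc > 0, nc, 1)
        freqs[g] = np.where(nc > 0, f, np.nan)
        n_chrom[g] = nc
    return AlleleFreqTable(freqs=freqs, n_chrom=n_chrom, snp_meta=G.snp_meta)


def assign_blocks(
    snp_meta: pd.DataFrame, size_cm: float | None = 5.0, size_snps: int | None = None
) -> np.ndarray:
    """Contiguous jackknife block ids per SNP, by genetic span (default 5 cM)
    or by fixed SNP count."""
    m = len(snp_meta)
    blocks = np.zeros(m, dtype=np.int64)
    b = 0
    if size_snps is not None:
        for start in range(0, m, size_snps):
            blocks[start : start + size_snps] = b
            b += 1
        return blocks
    if size_cm is None or size_cm <= 0:
        raise ValueError("size_cm must be positive")
    for chrom in snp_meta["chrom"].unique():
        idx = np.flatnonzero((snp_meta["chrom"] == chrom).to_numpy())
        cm = snp_meta["cm"].to_numpy()[idx]
        edge = cm[0]
        for pos, j in zip(cm, idx):
            if pos >= edge + size_cm:
                b += 1
                edge += size_cm * np.floor((pos - edge) / size_cm)
            blocks[j] = b
        b += 1
    return blocks


def _busing_jackknife(
    theta_hat: float, theta_del: np.ndarray, m_j: np.ndarray
) -> tuple[float, float]:
    """Weighted delete-one-block jackknife (Busing et al. 1999).

    Returns (bias-corrected estimate, standard error) given the full-data
    estimate, the delete-block estimates and block weights m_j.
    """
    g = len(theta_del)
    n = m_j.sum()
    h = n / m_j
    theta_J = g * theta_hat - np.sum((1.0 - m_j / n) * theta_del)
    tau = h * theta_hat - (h - 1.0) * theta_del
    var = np.sum((tau - theta_J) ** 2 / (h - 1.0)) / g
    return float(theta_J), float(np.sqrt(var))


def block_jackknife(
    per_snp_values: np.ndarray,
    weights: np.ndarray | None,
    block_assignment: np.ndarray,
) -> tuple[float, float]:
    """Weighted-mean estimate and block-jackknife SE of per-SNP values.

    ``weights`` default to 1 per SNP; blocks must be contiguous SNP ranges
    and at least two non-empty blocks are required.
    """
    v = np.asarray(per_snp_values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    blocks = np.asarray(block_assignment)
    uniq = np.unique(blocks)
    if len(uniq) < 2:
        raise ValueError("need >= 2 jackknife blocks")
    tot_num = float(np.sum(w * v))
    tot_den = float(np.sum(w))
    theta_hat = tot_num / tot_den
    theta_del = np.empty(len(uniq))
    m_j = np.empty(len(uniq))
    for k, bid in enumerate(uniq):
        sel = blocks == bid
        num = tot_num - float(np.sum(w[sel] * v[sel]))
        den = tot_den - float(np.sum(w[sel]))
        if den == 0:
            raise ValueError("a block contains all SNPs")
        theta_del[k] = num / den
        m_j[k] = w[sel].sum()
    _, se = _busing_jackknife(theta_hat, theta_del, m_j)
    return theta_hat, se


def _jackknife_ratio(
    num: np.ndarray, den: np.ndarray, blocks: np.ndarray
) -> tuple[float, float, int]:
    """Ratio-of-sums estimate with per-block delete-one jackknife."""
    uniq = np.unique(blocks)
    if len(uniq) < 2:
        raise ValueError("need >= 2 jackknife blocks")
    tn, td = float(num.sum()), float(den.sum())
    if td == 0:
        raise ValueError("zero denominator")
    theta_hat = tn / td
    theta_del, m_j = [], []
    for bid in uniq:
        sel = blocks == bid
        d = td - float(den[sel].sum())
        if d == 0:
            continue
        theta_del.append((tn - float(num[sel].sum())) / d)
        m_j.append(float(sel.sum()))  # block weight = SNP count
    theta_del = np.asarray(theta_del)
    m_j = np.asarray(m_j)
    if len(theta_del) < 2:
        raise ValueError("fewer than 2 usable blocks")
    _, se = _busing_jackknife(theta_hat, theta_del, m_j)
    return theta_hat, se, len(theta_del)


def _result(name, pops, est, se, n_blocks, n_snps, flags=None) -> FStatResult:
    z = est / se if se > 0 else np.inf * np.sign(est) if est != 0 else 0.0
    return FStatResult(
        name=name,
        pops=tuple(pops),
        estimate=float(est),
        se=float(se),
        z=float(z),
        n_blocks=n_blocks,
        n_snps=n_snps,
        flags=list(flags or []),
    )


def f3(
    A: str,
    B: str,
    C: str,
    freqs: AlleleFreqTable,
    blocks: np.ndarray | None = None,
    normalize: bool = False,
    correction: bool = True,
) -> FStatResult:
    """Admixture f3(C; A, B) with block-jackknife SE.

    ``correction`` subtracts the sampling-bias term c(1-c)/(n_C - 1);
    ``normalize`` divides by the target heterozygosity (off by default).
    """
    mask = freqs.require([A, B, C])
    if correction or normalize:
        mask &= freqs.n_chrom[C] >= 2
    if not mask.any():
        raise ValueError("no SNPs with sufficient target data")
    a = freqs.freqs[A][mask]
    b = freqs.freqs[B][mask]
    c = freqs.freqs[C][mask]
    nC = freqs.n_chrom[C][mask].astype(float)
    terms = (c - a) * (c - b)
    if correction:
        terms = terms - c * (1 - c) / (nC - 1)
    if blocks is None:
        blocks = assign_blocks(freqs.snp_meta)
    blk = blocks[mask]
    if normalize:
        het = 2 * c * (1 - c) * nC / (nC - 1)
        est, se, nb = _jackknife_ratio(terms, het, blk)
    else:
        est, se = block_jackknife(terms, None, blk)
        nb = len(np.unique(blk))
    return _result("f3", (C, A, B), est, se, nb, int(mask.sum()))


def f3_outgroup(
    O: str, pop1: str, pop2: str, freqs: AlleleFreqTable, blocks: np.ndarray | None = None
) -> FStatResult:
    """Outgroup f3(O; pop1, pop2): shared drift of pop1 and pop2 relative to O."""
    res = f3(pop1, pop2, O, freqs, blocks=blocks, correction=False)
    return _result("f3_outgroup", (O, pop1, pop2), res.estimate, res.se, res.n_blocks, res.n_snps)


def f4(
    A: str,
    B: str,
    C: str,
    D: str,
    freqs: AlleleFreqTable,
    blocks: np.ndarray | None = None,
) -> FStatResult:
    """f4(A, B; C, D) = mean (a-b)(c-d) with block-jackknife SE."""
    mask = freqs.require([A, B, C, D])
    if not mask.any():
        raise ValueError("no SNPs shared across all four populations")
    a, b = freqs.freqs[A][mask], freqs.freqs[B][mask]
    c, d = freqs.freqs[C][mask], freqs.freqs[D][mask]
    terms = (a - b) * (c - d)
    if blocks is None:
        blocks = assign_blocks(freqs.snp_meta)
    blk = blocks[mask]
    est, se = block_jackknife(terms, None, blk)
    return _result("f4", (A, B, C, D), est, se, len(np.unique(blk)), int(mask.sum()))


def f4_ratio(
    A: str,
    O: str,
    X: str,
    B: str,
    C: str,
    freqs: AlleleFreqTable,
    blocks: np.ndarray | None = None,
) -> FStatResult:
    """Admixture proportion alpha = f4(A,O;X,C) / f4(A,O;B,C).

    The ratio is jackknifed per block.  If the denominator is not bounded
    away from zero (|Z| < 3) the result carries an ``unstable-denominator``
    flag instead of failing silently.
    """
    mask = freqs.require([A, O, X, B, C])
    if not mask.any():
        raise ValueError("no SNPs shared across all five populations")
    a, o = freqs.freqs[A][mask], freqs.freqs[O][mask]
    x, b, c = freqs.freqs[X][mask], freqs.freqs[B][mask], freqs.freqs[C][mask]
    num = (a - o) * (x - c)
    den = (a - o) * (b - c)
    if blocks is None:
        blocks = assign_blocks(freqs.snp_meta)
    blk = blocks[mask]
    den_est, den_se = block_jackknife(den, None, blk)
    flags = []
    if den_se > 0 and abs(den_est / den_se) < 3:
        flags.append("unstable-denominator")
    est, se, nb = _jackknife_ratio(num, den, blk)
    return _result("f4_ratio", (A, O, X, B, C), est, se, nb, int(mask.sum()), flags)


def results_to_frame(results: list[FStatResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "statistic": r.name,
                "pops": ",".join(r.pops),
                "estimate": r.estimate,
                "std_err": r.se,
                "Z": r.z,
                "n_blocks": r.n_blocks,
                "n_snps": r.n_snps,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )
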