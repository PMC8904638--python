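"""Admixture dating from the decay of weighted linkage disequilibrium.

Admixture between two source populations g generations ago leaves excess
covariance between pairs of loci that decays with genetic distance d
(Morgans) as exp(-g d).  Following the ALDER-style two-reference statistic,
for SNP pairs (i, j) on the same chromosome binned by genetic distance,

    a(d) = mean over pairs in bin of  z_ij * w_i * w_j,

where z_ij is the genotype covariance between sites i and j in the target
cohort and w = (ref1 frequency - ref2 frequency) weights each site by the
allele-frequency contrast of the two reference populations.  The curve is
then fitted with the affine single-exponential model

    a(d) = A * exp(-g d) + c0

by nonlinear least squares from a multiplicative grid of starting values of
g; distances below ``d_min`` (default 0.5 cM) are excluded from the fit to
dodge background LD.  A flat curve (no significant amplitude by F-test at
0.05) is reported as non-converged rather than returning an arbitrary date.

Per-group date distributions are compared with two-sided Wilcoxon rank-sum
tests and Bonferroni correction over the number of pairs (the normal
approximation without tie correction is used; identical samples give
p = 1 exactly).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import MISSING, GenotypeMatrix


@dataclass
class WeightedLDCurve:
    bin_centers_cm: np.ndarray
    a: np.ndarray
    n_pairs: np.ndarray
    d_min_cm: float
    d_max_cm: float

    def fitting_mask(self) -> np.ndarray:
        return (
            (self.bin_centers_cm >= self.d_min_cm)
            & (self.bin_centers_cm <= self.d_max_cm)
            & (self.n_pairs > 0)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_cm": self.bin_centers_cm, "a": self.a, "n_pairs": self.n_pairs}
        )


@dataclass
class AdmixtureDateFit:
    amplitude: float
    c0: float
    generations: float | None
    rss: float
    converged: bool


def weighted_ld_curve(
    target: GenotypeMatrix,
    ref1_freqs: np.ndarray,
    ref2_freqs: np.ndarray,
    bin_width_cm: float = 0.25,
    d_min_cm: float = 0.5,
    d_max_cm: float = 30.0,
    map_units: str = "cM",
    block_rows: int = 1024,
) -> WeightedLDCurve:
    """Two-reference weighted-LD curve, same-chromosome pairs only.

    ``ref1_freqs``/``ref2_freqs`` are per-SNP frequencies of the counted
    allele in the two reference populations, aligned to the target's SNPs.
    ``map_units`` declares the unit of the genetic positions in
    ``target.snp_meta['cm']`` ("cM" or "M").
    """
    w = np.asarray(ref1_freqs, float) - np.asarray(ref2_freqs, float)
    if len(w) != target.n_snp:
        raise ValueError("reference frequencies must align with target SNPs")
    scale = 1.0 if map_units == "cM" else 100.0 if map_units in ("M", "Morgan") else None
    if scale is None:
        raise ValueError("map_units must be 'cM' or 'M'")
    pos_all = target.snp_meta["cm"].to_numpy() * scale
    d = target.dosage()
    col_mean = np.nanmean(d, axis=0)
    Z = np.nan_to_num(d - col_mean[None, :], nan=0.0)
    n_eff = (~np.isnan(d)).sum(axis=0).astype(float)
    n_bins = int(np.ceil(d_max_cm / bin_width_cm))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    n = target.n_ind
    for chrom in target.snp_meta["chrom"].unique():
        cidx = np.flatnonzero((target.snp_meta["chrom"] == chrom).to_numpy())
        pos = pos_all[cidx]
        Zc = Z[:, cidx]
        wc = w[cidx]
        m = len(cidx)
        for start in range(0, m, block_rows):
            stop = min(start + block_rows, m)
            # covariance of block rows against all sites (denominator n-1)
            cov = (Zc[:, start:stop].T @ Zc) / (n - 1)
            dist = np.abs(pos[start:stop, None] - pos[None, :])
            bins = np.floor(dist / bin_width_cm).astype(np.int64)
            # upper triangle only: global j > i
            jj = np.arange(m)[None, :]
            ii = np.arange(start, stop)[:, None]
            valid = (jj > ii) & (bins < n_bins)
            vals = cov * np.outer(wc[start:stop], wc)
            b = bins[valid]
            sums += np.bincount(b, weights=vals[valid], minlength=n_bins)
            counts += np.bincount(b, minlength=n_bins)
    if counts[(np.arange(n_bins) + 0.5) * bin_width_cm >= d_min_cm].sum() == 0:
        raise ValueError("no SNP pairs in the fitting range")
    with np.errstate(invalid="ignore"):
        a = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width_cm
    return WeightedLDCurve(
        bin_centers_cm=centers, a=a, n_pairs=counts, d_min_cm=d_min_cm, d_max_cm=d_max_cm
    )


def fit_exp_decay(curve: WeightedLDCurve, f_alpha: float = 0.05) -> AdmixtureDateFit:
    """Fit a(d) = A exp(-g d) + c0 (d in Morgans) by multi-start NLS.

    Starting values of g run a multiplicative grid 1, 1.5, 2.25, ... up to
    200; the best-RSS solution is kept.  Convergence requires the
    exponential amplitude to be significant by an F-test against the
    constant-only model at ``f_alpha``.
    """
    mask = curve.fitting_mask()
    d = curve.bin_centers_cm[mask] / 100.0  # Morgans
    y = curve.a[mask]
    if len(d) < 5:
        raise ValueError("need >= 5 bins in the fitting range")

    def model(params, dd):
        A, c0, g = params
        return A * np.exp(-g * dd) + c0

    def resid(params):
        return model(params, d) - y

    best = None
    g0 = 1.0
    starts = []
    while g0 <= 200.0:
        starts.append(g0)
        g0 *= 1.5
    A0 = max(float(y.max() - y.min()), 1e-12)
    for g_start in starts:
        try:
            sol = optimize.least_squares(
                resid,
                x0=[A0, float(y[-5:].mean()), g_start],
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e4]),
                max_nfev=2000,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return AdmixtureDateFit(0.0, float(y.mean()), None, float(np.sum((y - y.mean()) ** 2)), False)
    rss1, (A, c0, g) = best
    rss0 = float(np.sum((y - y.mean()) ** 2))
    n_pts = len(d)
    df1, df2 = 2, n_pts - 3
    if df2 <= 0 or rss1 <= 0:
        significant = rss1 < rss0
    else:
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
        significant = stats.f.sf(F, df1, df2) < f_alpha
    if not significant or A <= 0:
        return AdmixtureDateFit(float(A), float(c0), None, rss1, False)
    return AdmixtureDateFit(float(A), float(c0), float(g), rss1, True)


GENERATION_YEARS = 29.0  # conversion used when reporting dates in years


def compare_date_distributions(
    dates_by_group: dict[str, np.ndarray], correction: str = "bonferroni"
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with Bonferroni adjustment."""
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported")
    groups = list(dates_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if len(np.asarray(dates_by_group[g])) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    pairs = list(combinations(groups, 2))
    rows = []
    for g1, g2 in pairs:
        stat, p = stats.ranksums(dates_by_group[g1], dates_by_group[g2])
        rows.append((g1, g2, float(stat), float(p), min(1.0, float(p) * len(pairs))))
    return pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p_raw", "p_adj"])
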