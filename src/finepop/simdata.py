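"""Synthetic populations, admixed mosaic genomes, and copying vectors.

Source populations diverge from a shared ancestral allele-frequency pool
under the Balding-Nichols model: given ancestral frequency p and drift
parameter F in [0, 1), a source frequency is drawn

    p_s ~ Beta(p (1-F)/F, (1-p)(1-F)/F),

so E[p_s] = p and Var[p_s] = F p (1-p).  Haplotypes are independent
Bernoulli draws per site (no background LD), which makes admixture the only
source of long-range allelic association downstream.

Admixed genomes follow a single-pulse model g generations old: each
haplotype is a mosaic whose ancestry breakpoints form a Poisson process of
rate g per Morgan along the genetic map, each segment's source drawn
independently from the mixing proportions.  This yields ancestry
autocorrelation exp(-g d) at genetic distance d Morgans — the decay the
weighted-LD dating module fits.

Copying vectors (for painting-free tests of clustering/NNLS stages) are
Dirichlet draws around an exact mixture of source profiles.

Seeding: one seed governs a whole scenario; stage-local generators are
derived by fixed offsets (source frequencies +1, panels +2, mosaics +3,
copying vectors +4) so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, HaplotypePanel

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_source_freqs",
    "simulate_panel",
    "simulate_admixed",
    "simulate_copying_vectors",
    "uniform_map",
]


@dataclass
class SimConfig:
    """Parameters of one simulated admixture scenario."""

    n_sources: int = 2
    fst_per_source: tuple[float, ...] = (0.05, 0.05)
    n_snps: int = 5000
    n_per_pop: int = 100
    chrom_length_morgans: float = 1.0
    n_chrom: int = 3
    admix_proportions: tuple[float, ...] = (0.5, 0.5)
    admix_time_g: int = 13
    n_admixed: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources < 1 or self.n_snps < 1 or self.n_per_pop < 1 or self.n_chrom < 1:
            raise ValueError("all counts must be positive")
        if len(self.fst_per_source) != self.n_sources:
            raise ValueError("fst_per_source length must equal n_sources")
        if any(not 0.0 <= F < 1.0 for F in self.fst_per_source):
            raise ValueError("each F must lie in [0,1)")
        if len(self.admix_proportions) != self.n_sources:
            raise ValueError("admix_proportions length must equal n_sources")
        if abs(sum(self.admix_proportions) - 1.0) > 1e-12:
            raise ValueError("admix_proportions must sum to 1")
        if self.admix_time_g < 1:
            raise ValueError("admix_time_g must be a positive integer")
        if self.chrom_length_morgans <= 0:
            raise ValueError("chromosome length must be positive")


@dataclass
class SimTruth:
    """Ground truth attached to a simulated admixed panel.

    ``ancestry`` is (n_ind, n_sources) realized genome fractions;
    ``breakpoints[h]`` lists (start_morgans, end_morgans, source, chrom_idx)
    per segment of haplotype h, in chromosome then map order (positions
    restart per chromosome).
    """

    ancestry: np.ndarray
    breakpoints: list[list[tuple]] = field(default_factory=list)
    admix_time_g: int = 0

    def to_frame(self, ids: list[str]) -> pd.DataFrame:
        cols = {f"source{k}": self.ancestry[:, k] for k in range(self.ancestry.shape[1])}
        return pd.DataFrame({"id": ids, **cols})


def simulate_source_freqs(
    ancestral_freqs: np.ndarray, F: float | np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Balding-Nichols source frequencies; rows = sources, cols = SNPs.

    ``F`` may be a scalar (one source) or a vector (one row per source).
    F = 0 reproduces the ancestral frequencies exactly.
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("ancestral frequencies must lie strictly in (0,1)")
    Fs = np.atleast_1d(np.asarray(F, dtype=float))
    if np.any((Fs < 0.0) | (Fs >= 1.0)):
        raise ValueError("F must lie in [0,1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = np.empty((len(Fs), len(p)))
    for k, Fk in enumerate(Fs):
        if Fk == 0.0:
            out[k] = p
        else:
            a = p * (1.0 - Fk) / Fk
            b = (1.0 - p) * (1.0 - Fk) / Fk
            out[k] = rng.beta(a, b)
    return out[0] if np.ndim(F) == 0 else out


def default_snp_meta(
    n_snps: int, n_chrom: int = 1, chrom_length_morgans: float = 1.0
) -> pd.DataFrame:
    """Uniform genetic map: SNPs evenly spaced, 1 cM per Mb."""
    per = np.array_split(np.arange(n_snps), n_chrom)
    rows = []
    for c, idx in enumerate(per, start=1):
        m = len(idx)
        cm = np.linspace(0.0, chrom_length_morgans * 100.0, m, endpoint=False) + (
            chrom_length_morgans * 100.0 / (2 * m)
        )
        bp = np.round(cm * 1e4).astype(np.int64) + 1  # 1 cM per Mb
        bp = np.maximum.accumulate(bp)
        bp += np.arange(m)  # guard strict monotonicity
        for j, (c_, b_) in enumerate(zip(cm, bp)):
            rows.append((str(c), f"snp{c}_{j}", float(c_), int(b_), "A", "G"))
    return pd.DataFrame(rows, columns=["chrom", "id", "cm", "bp", "a1", "a2"])


def uniform_map(snp_meta: pd.DataFrame) -> pd.DataFrame:
    """Return (chrom, cm) map columns from SNP metadata (identity helper)."""
    return snp_meta[["chrom", "cm"]]


def simulate_panel(
    source_freqs: np.ndarray,
    n_per_pop: int,
    seed: int | np.random.Generator,
    snp_meta: pd.DataFrame | None = None,
    pop_label: str = "POP",
) -> tuple[HaplotypePanel, GenotypeMatrix]:
    """Draw a phased panel of ``n_per_pop`` diploids from site frequencies.

    Alleles are independent Bernoulli(freq) per site and haplotype;
    genotypes are the sums of the two haplotypes of each individual.
    """
    f = np.asarray(source_freqs, dtype=float)
    if f.ndim != 1:
        raise ValueError("source_freqs must be 1-D (one population)")
    if np.any((f < 0.0) | (f > 1.0)):
        raise ValueError("frequencies must lie in [0,1]")
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    haps = (rng.random((2 * n_per_pop, len(f))) < f[None, :]).astype(np.uint8)
    if snp_meta is None:
        snp_meta = default_snp_meta(len(f))
    sample_meta = pd.DataFrame(
        {
            "id": [f"{pop_label}_{i}" for i in range(n_per_pop)],
            "population": pop_label,
            "subgroup": pop_label,
        }
    )
    panel = HaplotypePanel(haps, snp_meta, sample_meta)
    return panel, panel.to_genotypes()


def _chrom_spans(snp_meta: pd.DataFrame) -> list[tuple[np.ndarray, float, float]]:
    """Per chromosome: (SNP index array, map start M, map end M)."""
    spans = []
    for chrom in snp_meta["chrom"].unique():
        idx = np.flatnonzero((snp_meta["chrom"] == chrom).to_numpy())
        cm = snp_meta["cm"].to_numpy()[idx]
        spans.append((idx, cm[0] / 100.0, cm[-1] / 100.0))
    return spans


def simulate_admixed(
    panels: list[HaplotypePanel],
    proportions: np.ndarray,
    g: int,
    n: int,
    seed: int | np.random.Generator,
    pop_label: str = "ADMIX",
) -> tuple[HaplotypePanel, SimTruth]:
    """Single-pulse admixed diploids as ancestry mosaics over source panels.

    Breakpoints along each chromosome are Poisson with rate ``g`` per
    Morgan; each segment's source is drawn independently from
    ``proportions`` and its alleles copied from a random haplotype of that
    source's panel.
    """
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9 or np.any(proportions < 0):
        raise ValueError("proportions must be a simplex vector")
    if len(panels) != len(proportions):
        raise ValueError("one panel per source required")
    if g < 1:
        raise ValueError("g must be >= 1")
    for k, pan in enumerate(panels):
        if proportions[k] > 0 and pan.haplotypes.shape[0] == 0:
            raise ValueError(f"source {k} has positive proportion but an empty panel")
    snp_meta = panels[0].snp_meta
    for pan in panels[1:]:
        if not pan.snp_meta.equals(snp_meta):
            raise ValueError("source panels must share SNP metadata")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    spans = _chrom_spans(snp_meta)
    cm_all = snp_meta["cm"].to_numpy()
    n_snp = len(snp_meta)
    K = len(panels)
    haps = np.empty((2 * n, n_snp), dtype=np.uint8)
    ancestry_len = np.zeros((2 * n, K))
    breakpoints: list[list[tuple[float, float, int]]] = []
    total_len = sum(end - start for _, start, end in spans)
    for h in range(2 * n):
        segs: list[tuple] = []
        for ci, (idx, start, end) in enumerate(spans):
            pos_m = cm_all[idx] / 100.0
            L = end - start
            # Poisson breakpoints via exponential gaps
            cuts = []
            t = start
            while True:
                t += rng.exponential(1.0 / g)
                if t >= end:
                    break
                cuts.append(t)
            bounds = [start] + cuts + [end]
            for s0, s1 in zip(bounds[:-1], bounds[1:]):
                src = int(rng.choice(K, p=proportions))
                donor = int(rng.integers(panels[src].haplotypes.shape[0]))
                # segment covers SNPs with s0 <= pos < s1 (last segment inclusive)
                if s1 == end:
                    mask = (pos_m >= s0) & (pos_m <= s1)
                else:
                    mask = (pos_m >= s0) & (pos_m < s1)
                if mask.any():
                    haps[h, idx[mask]] = panels[src].haplotypes[donor, idx[mask]]
                ancestry_len[h, src] += s1 - s0
                segs.append((s0, s1, src, ci))
        breakpoints.append(segs)
    ancestry_hap = ancestry_len / total_len
    ancestry_ind = 0.5 * (ancestry_hap[0::2] + ancestry_hap[1::2])
    sample_meta = pd.DataFrame(
        {
            "id": [f"{pop_label}_{i}" for i in range(n)],
            "population": pop_label,
            "subgroup": pop_label,
        }
    )
    panel = HaplotypePanel(haps, snp_meta, sample_meta)
    truth = SimTruth(ancestry=ancestry_ind, breakpoints=breakpoints, admix_time_g=g)
    return panel, truth


def simulate_copying_vectors(
    source_profiles: np.ndarray,
    weights: np.ndarray,
    concentration: float,
    n: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, SimTruth]:
    """Dirichlet copying vectors around an exact mixture of source profiles.

    The mean vector is ``weights @ source_profiles``; draws are
    Dirichlet(concentration * mean).  ``concentration = inf`` returns the
    exact mixture for every row (noise-free mode).
    """
    S = np.asarray(source_profiles, dtype=float)
    w = np.asarray(weights, dtype=float)
    if S.ndim != 2:
        raise ValueError("source_profiles must be 2-D (sources x donors)")
    if len(w) != S.shape[0]:
        raise ValueError("weights length must match number of source profiles")
    if np.any(np.abs(S.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each source profile must sum to 1")
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
        raise ValueError("weights must be a simplex vector")
    mean = w @ S
    if np.isinf(concentration):
        vecs = np.tile(mean, (n, 1))
    else:
        if concentration <= 0:
            raise ValueError("concentration must be positive")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        alpha = np.maximum(concentration * mean, 1e-12)
        vecs = rng.dirichlet(alpha, size=n)
    truth = SimTruth(ancestry=np.tile(w, (n, 1)))
    return vecs, truth


def simulate_scenario(config: SimConfig) -> dict:
    """Run a full scenario: ancestral pool -> sources -> panels -> admixed.

    Returns a dict with source panels, the admixed panel, source allele
    frequencies and the truth object.  Stage generators are derived from
    ``config.seed`` by fixed offsets.
    """
    rng_anc = np.random.default_rng(config.seed + 1)
    anc = rng_anc.uniform(0.05, 0.95, size=config.n_snps)
    src_freqs = simulate_source_freqs(
        anc, np.asarray(config.fst_per_source), np.random.default_rng(config.seed + 1)
    )
    snp_meta = default_snp_meta(config.n_snps, config.n_chrom, config.chrom_length_morgans)
    panels = []
    rng_pan = np.random.default_rng(config.seed + 2)
    for k in range(config.n_sources):
        pan, _ = simulate_panel(
            src_freqs[k], config.n_per_pop, rng_pan, snp_meta, pop_label=f"SRC{k}"
        )
        panels.append(pan)
    admixed, truth = simulate_admixed(
        panels,
        np.asarray(config.admix_proportions),
        config.admix_time_g,
        config.n_admixed,
        np.random.default_rng(config.seed + 3),
    )
    return {
        "ancestral_freqs": anc,
        "source_freqs": src_freqs,
        "source_panels": panels,
        "admixed_panel": admixed,
        "truth": truth,
        "snp_meta": snp_meta,
    }
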