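"""All-vs-all haplotype painting under a simplified Li-Stephens model.

Each recipient haplotype is modelled as a mosaic copied from the haplotypes
of all OTHER individuals (the donors).  Between adjacent SNPs separated by
genetic distance Delta d (Morgans) the copying process switches with
probability 1 - exp(-rho * Delta d) to a uniformly chosen donor haplotype
(possibly the current one), otherwise it stays; alleles are emitted with
probability 1 - mu on a match and mu on a mismatch.  The maximum-probability
donor path is recovered by Viterbi decoding (deterministic, unlike the
expected chunk counts of the forward-backward approach; ties are broken
toward the lowest donor index).

A *chunk* is a maximal run copied from one donor haplotype.  Chunk counts
and cM lengths are aggregated to donor individuals and summed over the
recipient's two haplotypes, giving the chunk-count and chunk-length
coancestry matrices.  Chunk lengths are measured between midpoints of the
SNP intervals flanking each switch; terminal chunks extend to the map ends,
so each recipient's chunk lengths sum to twice the map length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import HaplotypePanel


@dataclass
class PainterConfig:
    """Copying-model parameters: switch rate per Morgan and emission error."""

    switch_rate: float = 50.0
    emission_error: float = 0.001

    def __post_init__(self) -> None:
        if self.switch_rate <= 0:
            raise ValueError("switch_rate must be positive")
        if not 0.0 < self.emission_error < 0.5:
            raise ValueError("emission_error must lie in (0, 0.5)")


@dataclass
class CoancestryMatrix:
    """Recipient x donor chunk counts and cM chunk lengths (diagonal 0)."""

    chunk_counts: pd.DataFrame
    chunk_lengths_cm: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return list(self.chunk_counts.index)


def viterbi_path(
    recipient: np.ndarray,
    donors: np.ndarray,
    cm_pos: np.ndarray,
    rho: float,
    mu: float,
) -> np.ndarray:
    """Most probable donor index per SNP for one recipient haplotype.

    ``donors`` is (D, T); distances are taken from ``cm_pos`` (cM).  Ties
    are broken toward the lowest donor index.
    """
    D, T = donors.shape
    if T != len(recipient):
        raise ValueError("recipient/donor length mismatch")
    log_match = np.log1p(-mu)
    log_mis = np.log(mu)
    emis = np.where(donors == recipient[None, :], log_match, log_mis)  # (D, T)
    dd = np.diff(cm_pos) / 100.0  # Morgans
    p_sw = 1.0 - np.exp(-rho * dd)
    log_stay = np.log(np.exp(-rho * dd) + p_sw / D)
    log_switch = np.log(p_sw / D)
    V = emis[:, 0] - np.log(D)
    back = np.empty((T, D), dtype=np.int32)
    back[0] = np.arange(D)
    for t in range(1, T):
        jm = int(np.argmax(V))  # first (lowest) index on ties
        switch_score = V[jm] + log_switch[t - 1]
        stay_score = V + log_stay[t - 1]
        take_stay = stay_score > switch_score
        prev = np.where(take_stay, np.arange(D), jm)
        # exact ties between staying and switching: lowest index wins
        tie = stay_score == switch_score
        prev[tie] = np.minimum(np.arange(D)[tie], jm)
        V = np.where(take_stay, stay_score, switch_score)
        V[tie] = stay_score[tie]
        V = V + emis[:, t]
        back[t] = prev
    path = np.empty(T, dtype=np.int32)
    path[-1] = int(np.argmax(V))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _chunks_from_path(path: np.ndarray, cm_pos: np.ndarray) -> list[tuple[int, float]]:
    """(donor index, cM length) per chunk; midpoint boundaries, terminal
    chunks extended to the map ends."""
    T = len(path)
    switch_at = np.flatnonzero(path[1:] != path[:-1]) + 1  # index of first SNP of new chunk
    bounds = [cm_pos[0]]
    for s in switch_at:
        bounds.append(0.5 * (cm_pos[s - 1] + cm_pos[s]))
    bounds.append(cm_pos[-1])
    starts = np.concatenate([[0], switch_at])
    return [
        (int(path[s]), float(b1 - b0))
        for s, b0, b1 in zip(starts, bounds[:-1], bounds[1:])
    ]


def paint_all_vs_all(panel: HaplotypePanel, config: PainterConfig) -> CoancestryMatrix:
    """Paint every individual against all others; per-chromosome Viterbi.

    Returns chunk-count and chunk-length matrices aggregated to individuals
    (rows = recipients, columns = donors, diagonal identically zero).
    """
    n = panel.n_ind
    if n < 3:
        raise ValueError("all-vs-all painting needs >= 3 individuals")
    ids = panel.sample_meta["id"].tolist()
    counts = np.zeros((n, n))
    lengths = np.zeros((n, n))
    chrom_ids = panel.snp_meta["chrom"].unique()
    cm_all = panel.snp_meta["cm"].to_numpy()
    total_len = 0.0
    for chrom in chrom_ids:
        cidx = np.flatnonzero((panel.snp_meta["chrom"] == chrom).to_numpy())
        cm = cm_all[cidx]
        if cm[-1] - cm[0] <= 0:
            raise ValueError(f"chrom {chrom}: zero genetic map length")
        total_len += cm[-1] - cm[0]
        H = panel.haplotypes[:, cidx]
        for i in range(n):
            donor_rows = np.array([h for h in range(2 * n) if h // 2 != i])
            donor_ind = donor_rows // 2
            donors = H[donor_rows]
            for hap_row in (2 * i, 2 * i + 1):
                path = viterbi_path(
                    H[hap_row], donors, cm, config.switch_rate, config.emission_error
                )
                for d, length in _chunks_from_path(path, cm):
                    j = donor_ind[d]
                    counts[i, j] += 1
                    lengths[i, j] += length
    cc = pd.DataFrame(counts, index=ids, columns=ids)
    cl = pd.DataFrame(lengths, index=ids, columns=ids)
    return CoancestryMatrix(chunk_counts=cc, chunk_lengths_cm=cl)


def copying_vectors(
    M: CoancestryMatrix,
    assignment: dict[str, str],
    basis: str = "counts",
    drop_self_cluster: bool = False,
) -> pd.DataFrame:
    """Aggregate donor columns to donor clusters and renormalize to sum 1.

    ``assignment`` maps donor individual id -> cluster label and must cover
    every donor column.  With ``drop_self_cluster`` the recipient's own
    cluster column is removed before renormalization.
    """
    if basis not in ("counts", "lengths"):
        raise ValueError("basis must be 'counts' or 'lengths'")
    raw = M.chunk_counts if basis == "counts" else M.chunk_lengths_cm
    missing = [c for c in raw.columns if c not in assignment]
    if missing:
        raise ValueError(f"assignment does not cover donors: {missing[:5]}")
    clusters = sorted(set(assignment.values()))
    agg = pd.DataFrame(0.0, index=raw.index, columns=clusters)
    for col in raw.columns:
        agg[assignment[col]] += raw[col]
    if drop_self_cluster:
        for rid in agg.index:
            own = assignment.get(rid)
            if own in agg.columns:
                agg.loc[rid, own] = 0.0
    totals = agg.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero copying vector for {bad[:5]}")
    return agg.div(totals, axis=0)
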