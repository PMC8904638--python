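"""Constrained NNLS ancestry profiles from copying vectors.

A target copying vector y is decomposed as a non-negative mixture of
source-cluster copying profiles S (rows = sources) with proportions summing
to one.  The sum-to-one constraint is imposed softly by appending a penalty
row of weight ``penalty`` to the design (the standard "slight modification"
of plain NNLS used for painting profiles), then enforced exactly by
renormalizing the solution; the penalty default (100x the largest design
entry) keeps pre-renormalization sums within [0.99, 1.01] on sane inputs
and a warning is raised otherwise.

Donor-cluster columns belonging to the target's own cluster are removed
from y and S (both renormalized) before solving, preventing the trivial
self-copy solution; disable with ``drop_cols=None`` for vectors that were
already externalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls


@dataclass
class AncestryProfile:
    sources: list[str]
    weights: np.ndarray  # simplex
    residual: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.sources, self.weights))


def nnls_profile(
    y: np.ndarray | pd.Series,
    S: np.ndarray | pd.DataFrame,
    penalty: float | None = None,
    source_labels: list[str] | None = None,
    drop_cols: list[int] | None = None,
) -> AncestryProfile:
    """Sum-to-one NNLS decomposition of copying vector ``y`` over sources ``S``.

    ``S`` rows are source profiles on the same donor-cluster basis as
    ``y``.  ``drop_cols`` lists donor-basis columns to remove (the target's
    own cluster) before solving; y and S are renormalized afterwards.
    """
    if isinstance(S, pd.DataFrame):
        if source_labels is None:
            source_labels = [str(i) for i in S.index]
        S = S.to_numpy()
    S = np.asarray(S, float)
    y = np.asarray(y, float).ravel()
    if S.ndim != 2 or S.shape[1] != len(y):
        raise ValueError("y and source profiles must share the donor basis")
    if S.shape[0] < 2:
        raise ValueError("need >= 2 sources")
    flags = []
    if len(np.unique(S.round(12), axis=0)) < S.shape[0]:
        flags.append("degenerate-sources")
    if drop_cols:
        keep = np.ones(S.shape[1], dtype=bool)
        keep[np.asarray(drop_cols)] = False
        y = y[keep]
        S = S[:, keep]
        ysum = y.sum()
        if ysum <= 0:
            raise ValueError("target vector is all-zero after self-cluster removal")
        y = y / ysum
        rs = S.sum(axis=1)
        if np.any(rs <= 0):
            raise ValueError("a source profile is all-zero after self-cluster removal")
        S = S / rs[:, None]
    if penalty is None:
        penalty = 100.0 * float(np.abs(S).max())
    A = np.vstack([S.T, np.full((1, S.shape[0]), penalty)])
    b = np.concatenate([y, [penalty]])
    beta, _ = _nnls(A, b)
    total = beta.sum()
    if not 0.99 <= total <= 1.01:
        warnings.warn(f"pre-renormalization weight sum {total:.4f} outside [0.99, 1.01]")
    if total <= 0:
        raise ValueError("NNLS returned the zero solution")
    weights = beta / total
    residual = float(np.linalg.norm(y - weights @ S))
    labels = source_labels or [f"source{k}" for k in range(S.shape[0])]
    return AncestryProfile(sources=labels, weights=weights, residual=residual, flags=flags)


def cluster_profiles(
    vectors: pd.DataFrame,
    assignment,
    source_panels: dict[str, list[str]],
    per_individual_mean: bool = False,
    penalty: float | None = None,
    drop_self: bool = True,
) -> dict[str, pd.DataFrame]:
    """NNLS ancestry profiles of every non-source cluster (and its members)
    against one or more source panels.

    ``source_panels`` maps a panel name (e.g. "5-source", "3-source") to the
    list of source cluster labels; source profiles are the mean copying
    vectors of the source clusters' members.  Per-cluster profiles decompose
    the cluster mean vector by default; with ``per_individual_mean`` they
    are the mean of member profiles instead.  With ``drop_self`` (default),
    the donor-basis column matching the target's own cluster is removed
    before each solve (copying vectors should therefore be on the
    cluster-label donor basis).  Returns one long-format frame per panel
    with rows for clusters and individuals.
    """
    clusters = assignment.clusters
    cols = [str(c) for c in vectors.columns]
    out: dict[str, pd.DataFrame] = {}
    for panel_name, sources in source_panels.items():
        for s in sources:
            if s not in clusters or not clusters[s]:
                raise ValueError(f"source cluster {s!r} is missing or empty")
        S = pd.DataFrame(
            {s: vectors.loc[clusters[s]].mean(axis=0) for s in sources}
        ).T
        rows = []
        targets = [c for c in clusters if c not in sources]
        for cl in targets:
            drop = [cols.index(cl)] if (drop_self and cl in cols) else None
            member_profiles = []
            for ind in clusters[cl]:
                prof = nnls_profile(vectors.loc[ind], S, penalty=penalty,
                                    source_labels=sources, drop_cols=drop)
                member_profiles.append(prof.weights)
                rows.append(("individual", ind, cl, *prof.weights, prof.residual))
            if per_individual_mean:
                w = np.mean(member_profiles, axis=0)
                w = w / w.sum()
                rows.append(("cluster", cl, cl, *w, np.nan))
            else:
                mean_vec = vectors.loc[clusters[cl]].mean(axis=0)
                prof = nnls_profile(mean_vec, S, penalty=penalty,
                                    source_labels=sources, drop_cols=drop)
                rows.append(("cluster", cl, cl, *prof.weights, prof.residual))
        out[panel_name] = pd.DataFrame(
            rows, columns=["kind", "target", "cluster", *sources, "residual"]
        )
    return out
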