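"""Coancestry-based clustering, two-stage tree refinement, and TVD
heterogeneity statistics.

Individuals are clustered by deterministic hierarchical agglomeration on
the total variation distance (TVD) between their copying vectors — a
reproducible stand-in for fineSTRUCTURE's MCMC (an external assignment can
be supplied instead and refined identically).

Two refinement rules operate on an initial partition:

* size rule — climbing the cluster dendrogram bottom-up to a fixpoint, an
  internal node is collapsed into a single cluster when its descendant
  leaves number fewer than ``max_branch_clusters`` AND at least one of them
  has fewer than ``min_cluster_individuals`` members;
* TVD pooling — pairs (up to ``max_pool``-tuples) of clusters are pooled
  greedily, extreme pair first with re-evaluation after each merge, when
  the TVD between their mean chunk-count copying vectors falls on the
  configured side of a threshold (default 0.035).  The comparison
  direction is an explicit flag: the conventional reading merges clusters
  that are *similar* (TVD below threshold), but the rule can be flipped.

TVD between copying vectors x and y is ``0.5 * sum_k |x_k - y_k|``, a
metric on the simplex with values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


# ---------------------------------------------------------------------------
# TVD


def tvd(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("vectors of unequal length")
    return 0.5 * float(np.abs(x - y).sum())


def tvd_pairwise(vectors: np.ndarray | pd.DataFrame, basis: str | None = None) -> np.ndarray:
    """Symmetric pairwise TVD matrix over rows (zero diagonal)."""
    X = np.asarray(vectors, float)
    if X.ndim != 2:
        raise ValueError("vectors must be 2-D")
    return 0.5 * np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)


# ---------------------------------------------------------------------------
# assignment / tree containers


@dataclass
class ClusterAssignment:
    """Partition of individuals into named clusters."""

    of: dict[str, str]  # individual id -> cluster id

    def __post_init__(self) -> None:
        if not self.of:
            raise ValueError("empty assignment")

    @property
    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ind, cl in self.of.items():
            out.setdefault(cl, []).append(ind)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.of.values()))

    def sizes(self) -> dict[str, int]:
        return {cl: len(m) for cl, m in self.clusters.items()}

    def relabel_merge(self, group: list[str]) -> "ClusterAssignment":
        """Merge the named clusters into one (joined label)."""
        new_label = "+".join(sorted(group))
        of = {
            ind: (new_label if cl in group else cl) for ind, cl in self.of.items()
        }
        return ClusterAssignment(of)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.of.items()), columns=["id", "cluster"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterAssignment":
        return cls(dict(zip(df["id"].astype(str), df["cluster"].astype(str))))


@dataclass
class TreeNode:
    """Binary dendrogram node; leaves carry cluster labels."""

    label: str | None = None
    height: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return self.left.leaves() + self.right.leaves()

    def to_newick(self) -> str:
        def rec(node: "TreeNode") -> str:
            if node.is_leaf:
                return node.label or ""
            return f"({rec(node.left)},{rec(node.right)}):{node.height:.6g}"

        return rec(self) + ";"


@dataclass
class ClusterTree:
    root: TreeNode
    leaf_labels: list[str] = field(default_factory=list)

    def to_newick(self) -> str:
        return self.root.to_newick()

    @classmethod
    def from_newick(cls, text: str) -> "ClusterTree":
        """Parse the binary Newick trees this module writes
        (``(left,right):height`` internal nodes, bare leaf labels)."""
        s = text.strip().rstrip(";")
        pos = 0

        def parse() -> TreeNode:
            nonlocal pos
            if s[pos] == "(":
                pos += 1  # "("
                left = parse()
                if s[pos] != ",":
                    raise ValueError(f"expected ',' at {pos} in newick")
                pos += 1
                right = parse()
                if s[pos] != ")":
                    raise ValueError(f"expected ')' at {pos} in newick")
                pos += 1
                height = 0.0
                if pos < len(s) and s[pos] == ":":
                    pos += 1
                    j = pos
                    while j < len(s) and s[j] not in ",()":
                        j += 1
                    height = float(s[pos:j])
                    pos = j
                return TreeNode(height=height, left=left, right=right)
            j = pos
            while j < len(s) and s[j] not in ",():":
                j += 1
            label = s[pos:j]
            pos = j
            return TreeNode(label=label)

        root = parse()
        return cls(root=root, leaf_labels=root.leaves())


def _tree_from_linkage(Z: np.ndarray, labels: list[str]) -> ClusterTree:
    n = len(labels)
    nodes: dict[int, TreeNode] = {i: TreeNode(label=labels[i]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        nodes[n + k] = TreeNode(height=float(h), left=nodes[int(a)], right=nodes[int(b)])
    return ClusterTree(root=nodes[n + len(Z) - 1] if len(Z) else nodes[0], leaf_labels=labels)


# ---------------------------------------------------------------------------
# clustering


def build_tree(
    vectors: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
    linkage_method: str = "average",
) -> tuple[ClusterTree, ClusterAssignment]:
    """Agglomerate individuals on TVD distance between copying vectors.

    ``vectors`` rows are individuals (index = ids).  The initial partition
    is cut at ``n_clusters`` (or at ``height``); the returned tree has the
    resulting clusters as leaves (agglomeration of cluster mean vectors).
    """
    if linkage_method not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    ids = [str(i) for i in vectors.index]
    if len(ids) < 2:
        raise ValueError("need >= 2 individuals")
    X = np.asarray(vectors, float)
    D = tvd_pairwise(X)
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    if n_clusters is not None:
        if n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    elif height is not None:
        flat = fcluster(Z, t=height, criterion="distance")
    else:
        flat = fcluster(Z, t=0.0, criterion="distance")
    # stable cluster labels: order of first appearance
    label_of: dict[int, str] = {}
    of = {}
    for ind, f in zip(ids, flat):
        if f not in label_of:
            label_of[f] = f"C{len(label_of) + 1}"
        of[ind] = label_of[f]
    assignment = ClusterAssignment(of)
    # tree over clusters: linkage of cluster mean vectors
    clusters = assignment.clusters
    cl_labels = sorted(clusters, key=lambda c: int(c[1:]))
    if len(cl_labels) == 1:
        tree = ClusterTree(root=TreeNode(label=cl_labels[0]), leaf_labels=cl_labels)
        return tree, assignment
    means = np.vstack([X[[ids.index(i) for i in clusters[c]]].mean(axis=0) for c in cl_labels])
    Zc = linkage(squareform(tvd_pairwise(means), checks=False), method=linkage_method)
    return _tree_from_linkage(Zc, cl_labels), assignment


# ---------------------------------------------------------------------------
# refinement


def refine_tree_size(
    tree: ClusterTree,
    assignment: ClusterAssignment,
    max_branch_clusters: int = 5,
    min_cluster_individuals: int = 5,
) -> ClusterAssignment:
    """Collapse small branches of the cluster dendrogram, to a fixpoint.

    An internal node whose descendant leaf clusters number fewer than
    ``max_branch_clusters`` and of which at least one has fewer than
    ``min_cluster_individuals`` members is collapsed into one cluster.
    """
    sizes = assignment.sizes()
    tree_leaves = set(tree.root.leaves())
    # clusters may carry merged labels ("A+B") from a previous pass
    parts = {p for cl in sizes for p in cl.split("+")}
    if tree_leaves != parts:
        raise ValueError("tree leaves and assignment clusters are inconsistent")
    current = assignment
    changed = True
    while changed:
        changed = False
        sizes = current.sizes()
        merged: dict[str, str] = {}  # original leaf label -> merged cluster label

        def current_cluster(leaf: str) -> str:
            # original tree leaves map into possibly-merged cluster labels
            for cl in sizes:
                if leaf == cl or leaf in cl.split("+"):
                    return cl
            raise KeyError(leaf)

        # walk internal nodes bottom-up (by height order)
        nodes: list[TreeNode] = []

        def collect(node: TreeNode) -> None:
            if not node.is_leaf:
                collect(node.left)
                collect(node.right)
                nodes.append(node)

        collect(tree.root)
        for node in nodes:
            leaf_clusters = sorted({current_cluster(l) for l in node.leaves()})
            if len(leaf_clusters) < 2:
                continue
            if len(leaf_clusters) < max_branch_clusters and any(
                sizes[c] < min_cluster_individuals for c in leaf_clusters
            ):
                current = current.relabel_merge(leaf_clusters)
                changed = True
                break
    return current


def cluster_mean_vectors(
    vectors: pd.DataFrame, assignment: ClusterAssignment, use_median: bool = False
) -> pd.DataFrame:
    clusters = assignment.clusters
    rows = {}
    for cl, members in clusters.items():
        sub = vectors.loc[members]
        rows[cl] = sub.median(axis=0) if use_median else sub.mean(axis=0)
    return pd.DataFrame(rows).T


def refine_tree_tvd(
    assignment: ClusterAssignment,
    vectors: pd.DataFrame,
    threshold: float = 0.035,
    max_pool: int = 3,
    merge_if_below: bool = True,
    use_median: bool = False,
) -> ClusterAssignment:
    """Greedy TVD pooling of clusters (pairs up to ``max_pool``-tuples).

    Cluster-level TVD is measured between cluster mean (or median) copying
    vectors.  In merge-if-below mode the closest eligible pair is pooled
    first; after each merge distances are re-evaluated.  A pool never
    absorbs more than ``max_pool`` original clusters.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0,1)")
    current = assignment
    n_orig = {cl: len(cl.split("+")) for cl in current.clusters}

    def pool_size(cl: str) -> int:
        return sum(n_orig.get(part, 1) for part in cl.split("+"))

    while current.n_clusters >= 2:
        means = cluster_mean_vectors(vectors, current, use_median=use_median)
        labels = list(means.index)
        D = tvd_pairwise(means.to_numpy())
        best = None
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if pool_size(labels[i]) + pool_size(labels[j]) > max_pool:
                    continue
                d = D[i, j]
                eligible = d < threshold if merge_if_below else d > threshold
                if not eligible:
                    continue
                key = d if merge_if_below else -d
                if best is None or key < best[0]:
                    best = (key, labels[i], labels[j])
        if best is None:
            break
        current = current.relabel_merge([best[1], best[2]])
    return current


# ---------------------------------------------------------------------------
# TVD heterogeneity levels


@dataclass
class TVDReport:
    level: str  # intra-cluster-all | focal-vs-all | focal-only
    basis: str
    values: dict[str, np.ndarray]  # cluster -> pairwise TVD values

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cl, vals in self.values.items():
            for v in vals:
                rows.append((self.level, self.basis, cl, v))
        return pd.DataFrame(rows, columns=["level", "basis", "cluster", "tvd"])


def tvd_levels(
    vectors_by_basis: dict[str, pd.DataFrame],
    assignment: ClusterAssignment,
    focal_labels: set[str] | list[str],
) -> list[TVDReport]:
    """Three per-cluster TVD distributions, per basis.

    Level 1 (intra-cluster-all): all member pairs of each cluster.
    Level 2 (focal-vs-all): pairs of one focal and one other member.
    Level 3 (focal-only): pairs of focal members.
    Clusters with no eligible pairs are reported with empty value arrays.
    """
    focal = set(map(str, focal_labels))
    all_ids = set(assignment.of)
    unknown = focal - all_ids
    if unknown:
        raise ValueError(f"unknown focal labels: {sorted(unknown)[:5]}")
    reports = []
    for basis, vectors in vectors_by_basis.items():
        D = tvd_pairwise(vectors.to_numpy())
        ids = [str(i) for i in vectors.index]
        pos = {i: k for k, i in enumerate(ids)}
        lvl: dict[str, dict[str, list[float]]] = {
            "intra-cluster-all": {},
            "focal-vs-all": {},
            "focal-only": {},
        }
        for cl, members in assignment.clusters.items():
            members = [m for m in members if m in pos]
            f_m = [m for m in members if m in focal]
            o_m = [m for m in members if m not in focal]
            lvl["intra-cluster-all"][cl] = [
                D[pos[a], pos[b]] for i, a in enumerate(members) for b in members[i + 1 :]
            ]
            lvl["focal-vs-all"][cl] = [D[pos[a], pos[b]] for a in f_m for b in o_m] + [
                D[pos[a], pos[b]] for i, a in enumerate(f_m) for b in f_m[i + 1 :]
            ]
            lvl["focal-only"][cl] = [
                D[pos[a], pos[b]] for i, a in enumerate(f_m) for b in f_m[i + 1 :]
            ]
        for level, values in lvl.items():
            reports.append(
                TVDReport(
                    level=level,
                    basis=basis,
                    values={cl: np.asarray(v) for cl, v in values.items()},
                )
            )
    return reports
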