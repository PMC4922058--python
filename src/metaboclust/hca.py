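"""Hierarchical clustering of preprocessed spectra (Euclidean / Ward).

Samples are merged agglomeratively, at each step joining the pair of
clusters whose union minimizes the increase in within-cluster sum of squares
(dESS, Ward's criterion on Euclidean input).  The dendrogram is cut into k
metabolic clusters; labels are assigned deterministically by decreasing
cluster size, ties broken by first-sample order, and named "Mc1"..."Mck".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


@dataclass
class ClusterResult:
    """Ward merge tree and (optionally) a k-cut labelling.

    ``merges`` has one row per merge: (node_a, node_b, cost, size) where
    nodes 0..n-1 are leaves, node n+i is the cluster created by merge i, and
    cost is the within-cluster sum-of-squares increase (dESS) of the merge.
    """

    merges: np.ndarray
    sample_ids: list[str]
    labels: pd.Series | None = None
    k: int | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def scipy_linkage(self) -> np.ndarray:
        """Linkage matrix in scipy convention (heights = sqrt(2 * dESS))."""
        z = self.merges.copy()
        z[:, 2] = np.sqrt(2.0 * z[:, 2])
        return z


def ward_tree(X: np.ndarray, sample_ids: list[str] | None = None) -> ClusterResult:
    """Agglomerate by minimum dESS (Ward) and record merge costs.

    The merge cost stored is the dESS of the merge itself: for singletons a
    and b this is ||a - b||^2 / 2.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two samples")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(X.shape[0])]
    z = hierarchy.linkage(X, method="ward")
    merges = z.copy()
    merges[:, 2] = z[:, 2] ** 2 / 2.0  # scipy ward heights are sqrt(2*dESS)
    return ClusterResult(merges=merges, sample_ids=list(sample_ids))


def cut_tree(tree: ClusterResult, k: int) -> pd.Series:
    """Labels from undoing the last k-1 merges, relabelled deterministically.

    Cluster ids "Mc1".."Mck" are assigned by decreasing cluster size; equal
    sizes are ordered by the position of their first sample.
    """
    n = tree.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.fcluster(tree.scipy_linkage, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        # exact cut by undoing merges (fcluster can return fewer clusters on ties)
        raw = hierarchy.cut_tree(tree.scipy_linkage, n_clusters=k).ravel()
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.nonzero(raw == c)[0][0])),
    )
    remap = {c: f"Mc{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=tree.sample_ids, name="cluster")
    tree.labels, tree.k = labels, k
    return labels


def merges_frame(tree: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame(tree.merges, columns=["node_a", "node_b", "cost", "size"])


def to_newick(tree: ClusterResult) -> str:
    """Newick export with branch lengths derived from merge costs."""
    z = tree.scipy_linkage
    root = hierarchy.to_tree(z)

    def rec(node) -> str:
        if node.is_leaf():
            return tree.sample_ids[node.id]
        bl = node.dist - (0.0 if node.left.is_leaf() else node.left.dist)
        br = node.dist - (0.0 if node.right.is_leaf() else node.right.dist)
        return f"({rec(node.left)}:{bl:.6g},{rec(node.right)}:{br:.6g})"

    return rec(root) + ";"


__all__ = ["ClusterResult", "ward_tree", "cut_tree", "merges_frame", "to_newick"]
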