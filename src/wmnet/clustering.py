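"""Hierarchical clustering of condition-averaged activation and purity scoring.

Two-way structure discovery is two independent one-axis agglomerative
clusterings (Ward linkage on Euclidean distances) of the events x ROIs
matrix. Flat clusters come from the dendrogram inconsistency statistic:
a link is cut when (its height - mean subtree height) / subtree height
sd exceeds a threshold, computed over a fixed subtree depth. External
quality against known condition labels is purity: the fraction of items
falling in their cluster's majority class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


@dataclass
class ClusterResult:
    """Ward linkage tree plus the flat labeling derived from it."""

    linkage: np.ndarray
    labels: np.ndarray
    axis: str
    cutoff: float
    depth: int

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels)))


def ward_hcl(matrix: np.ndarray, axis: str = "rows") -> np.ndarray:
    """Full agglomerative tree, Ward linkage on Euclidean distances.

    ``axis`` chooses whether rows or columns are the clustered items.
    Returns the scipy linkage matrix; a single item yields an empty tree.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if np.isnan(matrix).any():
        raise ValueError("matrix contains missing values")
    if matrix.shape[0] < 2:
        return np.empty((0, 4))
    return hierarchy.linkage(matrix, method="ward", metric="euclidean")


def inconsistency(linkage: np.ndarray, depth: int = 5) -> np.ndarray:
    """Per-link inconsistency coefficients; zero-variance subtrees give 0."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if linkage.size == 0:
        return np.empty((0, 4))
    R = hierarchy.inconsistent(linkage, d=depth)
    R[:, 3] = np.nan_to_num(R[:, 3], nan=0.0)
    return R


def inconsistency_cut(
    linkage: np.ndarray, threshold: float = 1.15, depth: int = 5
) -> np.ndarray:
    """Flat labels: cut links whose inconsistency exceeds the threshold.

    All merge heights equal (inconsistency 0 everywhere) yields a single
    cluster; threshold -> infinity likewise.
    """
    if linkage.size == 0:
        return np.array([1])
    R = inconsistency(linkage, depth)
    return hierarchy.fcluster(linkage, t=threshold, criterion="inconsistent", R=R)


def cluster_axis(
    matrix: np.ndarray,
    axis: str = "rows",
    threshold: float = 1.15,
    depth: int = 5,
) -> ClusterResult:
    """Ward tree + inconsistency cut for one axis of a data matrix."""
    Z = ward_hcl(matrix, axis)
    labels = inconsistency_cut(Z, threshold, depth)
    return ClusterResult(linkage=Z, labels=labels, axis=axis, cutoff=threshold, depth=depth)


def purity(omega: np.ndarray, classes: np.ndarray) -> float:
    """Cluster purity: (1/N) sum_i max_j |omega_i ∩ c_j|.

    Each cluster is matched to its most frequent class; purity is the
    fraction of all items covered by those matches. Invariant to
    relabeling of either side; bounded below by the largest class share.
    """
    omega = np.asarray(omega)
    classes = np.asarray(classes)
    if omega.size == 0 or classes.size == 0:
        raise ValueError("labelings must be non-empty")
    if omega.shape != classes.shape:
        raise ValueError("cluster and class labelings must have equal length")
    table = pd.crosstab(pd.Series(omega), pd.Series(classes))
    return float(table.max(axis=1).sum() / omega.size)


def condition_average(
    features: np.ndarray,
    meta: pd.DataFrame,
    by: tuple[str, ...] = ("subject", "domain", "stage"),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Average feature rows over the factorial cells given by ``by``.

    Mirrors collapsing the event stack across runs and loads before
    clustering: one row per (subject x domain x stage) cell.
    """
    df = pd.DataFrame(features)
    df[list(by)] = meta[list(by)].to_numpy()
    grouped = df.groupby(list(by), sort=True, observed=True).mean()
    cell_meta = grouped.index.to_frame(index=False)
    return grouped.to_numpy(), cell_meta


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Export the dendrogram as a Newick string for inspection."""
    if linkage.size == 0:
        return f"({leaf_names[0]});" if leaf_names else "();"
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
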