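"""Unsupervised structure: most-variant genes, standardization, clustering.

The standard exploratory view of an expression cohort: pick the k genes with
the largest variance across samples (on the raw values), standardize each
gene to zero mean and unit variance, and cluster samples agglomeratively
(Euclidean metric, complete linkage by default).  Trees serialize to Newick
text so they are diffable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = ["ClusterConfig", "ClusterResult", "top_variant_genes", "standardize",
           "hierarchical_cluster"]


@dataclass(frozen=True)
class ClusterConfig:
    """k_genes: 500 for a whole-cohort view, 200 for a restricted one."""

    k_genes: int = 500
    metric: str = "euclidean"
    linkage: str = "complete"

    def __post_init__(self) -> None:
        if self.k_genes < 2:
            raise ValueError("k_genes must be >= 2")


def top_variant_genes(matrix: pd.DataFrame, k: int) -> list[str]:
    """The k genes with the largest sample variance (ddof=1), on raw values.

    Ties at the cutoff are broken by gene-id order (lexicographically first
    retained).
    """
    if k > len(matrix.index):
        raise ValueError(f"k={k} exceeds the {len(matrix.index)} genes available")
    var = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda g: (-var[g], g))
    return [str(g) for g in order[:k]]


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene (row) to zero mean and unit variance (ddof=1)."""
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(
            f"zero-variance gene(s) cannot be standardized: {zero.index.tolist()[:5]}; "
            "filter them first"
        )
    return matrix.sub(mu, axis=0).div(sd, axis=0)


@dataclass
class ClusterResult:
    """Sample-wise agglomeration: SciPy linkage matrix plus conveniences."""

    linkage_matrix: np.ndarray
    sample_ids: list[str]
    metric: str
    method: str

    def flat_clusters(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return dict(zip(self.sample_ids, map(int, labels)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{parent_height:.10g}"
            inner = f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
            return f"{inner}:{parent_height - node.dist:.10g}"

        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"


def hierarchical_cluster(matrix: pd.DataFrame, config: ClusterConfig | None = None) -> ClusterResult:
    """Agglomerative clustering of samples (columns).

    Deterministic given input order.  Merge heights of complete linkage are
    nondecreasing along the merge sequence.
    """
    if config is None:
        config = ClusterConfig()
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = hierarchy.linkage(matrix.to_numpy(float).T, method=config.linkage,
                          metric=config.metric)
    return ClusterResult(
        linkage_matrix=Z,
        sample_ids=[str(s) for s in matrix.columns],
        metric=config.metric,
        method=config.linkage,
    )
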