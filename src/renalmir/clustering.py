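"""Unsupervised expression clustering: log transform, Pearson-correlation
distance, agglomerative clustering, and cluster-vs-histology agreement.

Samples are clustered on log-transformed absolute copies using one minus the
Pearson correlation between sample profiles as the distance. Average linkage
is the default; the dendrogram can be cut at k groups and compared to the
histological labels by majority-label purity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DegenerateDataError, DomainError, InsufficientDataError

LINKAGE_METHODS = ("average", "complete", "single", "ward")


def log_transform(expression: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(copies + pseudocount), zero-safe for non-expressed markers."""
    numeric = expression.select_dtypes(include=[np.number])
    if (numeric.values < 0).any():
        raise DomainError("expression values must be >= 0 before log transform")
    return np.log2(numeric + pseudocount)


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample distance d(i, j) = 1 - Pearson r(i, j).

    Rows are samples, columns markers. Symmetric, zero diagonal, values in
    [0, 2]. A sample with a constant profile has undefined correlation and
    raises, naming the sample.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[1] < 2:
        raise InsufficientDataError("need >= 2 markers per sample for a correlation distance")
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if len(flat):
        raise DegenerateDataError(
            f"constant expression profile; correlation undefined for sample(s) "
            f"{[str(matrix.index[i]) for i in flat]}"
        )
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # enforce symmetry against float noise
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class Dendrogram:
    """Agglomerative clustering result over a fixed leaf order."""

    linkage: np.ndarray        # scipy linkage matrix
    labels: tuple[str, ...]    # leaf (sample) ids in input order
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Cluster assignment (1..k) per sample at k groups."""
        if not 1 <= k <= self.n_leaves:
            raise DomainError(f"k must be in [1, {self.n_leaves}], got {k}")
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=list(self.labels), name="cluster")

    def to_newick(self) -> str:
        """Newick serialization with merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(distances: pd.DataFrame, method: str = "average") -> Dendrogram:
    """Agglomerate samples from a precomputed distance matrix."""
    if method not in LINKAGE_METHODS:
        raise DomainError(f"linkage method must be one of {LINKAGE_METHODS}, got {method!r}")
    d = np.asarray(distances, dtype=float)
    if d.shape[0] < 2:
        raise InsufficientDataError("need >= 2 samples to cluster")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise DomainError("distance matrix must be square and symmetric")
    condensed = squareform(d, checks=False)
    z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(linkage=z, labels=tuple(str(s) for s in distances.index), method=method)


def cluster_label_agreement(
    assignments: pd.Series, labels: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Majority-label purity per cluster and overall (sample-weighted mean).

    ``assignments`` maps sample -> cluster id, ``labels`` maps sample ->
    histology. Returns (per-cluster table with size, majority label and
    purity; overall purity).
    """
    labels = labels.reindex(assignments.index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise DomainError(f"histology label missing for sample(s) {missing}")
    rows = []
    total = 0
    agree = 0
    for cl, idx in assignments.groupby(assignments).groups.items():
        sub = labels.loc[idx]
        counts = sub.value_counts()
        majority = counts.index[0]
        rows.append(
            {
                "cluster": cl,
                "n": len(sub),
                "majority_label": majority,
                "purity": counts.iloc[0] / len(sub),
            }
        )
        total += len(sub)
        agree += int(counts.iloc[0])
    table = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
    return table, agree / total


def cluster_expression(
    expression: pd.DataFrame,
    markers: list[str] | None = None,
    pseudocount: float = 1.0,
    method: str = "average",
) -> Dendrogram:
    """Convenience pipeline: log transform -> Pearson distance -> linkage."""
    mat = expression[markers] if markers is not None else expression
    logged = log_transform(mat, pseudocount=pseudocount)
    return hierarchical_cluster(pearson_distance(logged), method=method)
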