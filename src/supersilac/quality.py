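"""Replicate-reproducibility QC: correlation heat-map inputs and clustering.

Reproducibility between runs is assessed the way spike-in proteomics
studies usually present it: pairwise Pearson correlation of the normalized
log2 ratio columns over the proteins each pair shares, followed by
average-linkage hierarchical clustering on the distance d = 1 - r. In a
well-behaved experiment the biological and technical replicates of each
sample co-cluster — each replicate group forms its own subtree before any
merge with another group. `cocluster_score` turns that visual criterion
into a number in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .quant import QuantMatrix

__all__ = [
    "CorrelationMatrix",
    "LinkageResult",
    "pearson_matrix",
    "hcluster",
    "cocluster_score",
]


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations between sample columns."""

    r: pd.DataFrame  # symmetric, diagonal 1, NaN where a pair was unusable
    n_pairs: pd.DataFrame  # proteins observed in both columns of each pair

    @property
    def labels(self) -> list[str]:
        return list(self.r.columns)

    def is_complete(self) -> bool:
        return bool(self.r.notna().all().all())

    def to_tsv(self, path) -> None:
        self.r.to_csv(path, sep="\t", index_label="sample")


@dataclass
class LinkageResult:
    """Agglomerative clustering output: merge trace and ordered leaves."""

    merges: list[tuple[int, int, float]]  # (node, node, height); leaves are 0..n-1
    leaf_order: list[str]
    labels: list[str]
    linkage_matrix: np.ndarray  # scipy format, for dendrogram plotting


def pearson_matrix(matrix: QuantMatrix, min_pairs: int = 200) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation between all sample columns.

    Pairs sharing fewer than ``min_pairs`` observed proteins, or where a
    column has zero variance over the shared entries, are set to missing
    with a warning rather than reported as unstable numbers.
    """
    data = matrix.data
    observed = data.notna().astype(int)
    n_pairs = observed.T @ observed
    r = data.corr(method="pearson", min_periods=max(min_pairs, 2))
    np.fill_diagonal(r.values, 1.0)
    thin = (n_pairs < min_pairs) & ~np.eye(len(r), dtype=bool)
    if thin.to_numpy().any():
        warnings.warn(
            f"{int(thin.to_numpy().sum()) // 2} sample pair(s) share fewer than "
            f"{min_pairs} proteins; their correlations are reported as missing"
        )
        r = r.mask(thin)
    degenerate = r.isna() & (n_pairs >= min_pairs) & ~np.eye(len(r), dtype=bool)
    if degenerate.to_numpy().any():
        warnings.warn("zero-variance column over shared entries; correlation set to missing")
    return CorrelationMatrix(r=r, n_pairs=n_pairs)


def hcluster(corr: CorrelationMatrix, method: str = "average") -> LinkageResult:
    """Average-linkage hierarchical clustering on distance d = 1 - r.

    Labels are sorted lexicographically before clustering so that ties in
    merge heights resolve deterministically regardless of input order.
    """
    if not corr.is_complete():
        raise ValueError("correlation matrix has missing entries; cannot cluster")
    labels = sorted(corr.labels)
    r = corr.r.loc[labels, labels].to_numpy()
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    if len(labels) < 2:
        return LinkageResult([], list(labels), list(labels), np.empty((0, 4)))
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    return LinkageResult(merges, order, list(labels), z)


def _node_leafsets(linkage: LinkageResult) -> list[frozenset[str]]:
    """Leaf-label set under every node (leaves and internal merges)."""
    n = len(linkage.labels)
    sets: list[frozenset[str]] = [frozenset([lab]) for lab in linkage.labels]
    for a, b, _ in linkage.merges:
        sets.append(sets[a] | sets[b])
    return sets


def cocluster_score(linkage: LinkageResult, replicate_groups: dict[str, list[str]]) -> float:
    """Fraction of replicate groups forming a complete subtree of the dendrogram.

    A group 'co-clusters' when some node of the tree contains exactly its
    members — i.e. all its replicates merge with each other before any of
    them merges with an outside sample. Groups of a single leaf are trivial
    and excluded; if only such groups exist the score is undefined.
    """
    leaves = set(linkage.labels)
    assigned = [s for members in replicate_groups.values() for s in members]
    if set(assigned) != leaves or len(assigned) != len(leaves):
        raise ValueError("replicate_groups must partition the clustered leaves")
    scored = {g: frozenset(m) for g, m in replicate_groups.items() if len(m) >= 2}
    if not scored:
        raise ValueError("all replicate groups are singletons; co-clustering undefined")
    node_sets = set(_node_leafsets(linkage))
    hits = sum(1 for m in scored.values() if m in node_sets)
    return hits / len(scored)
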