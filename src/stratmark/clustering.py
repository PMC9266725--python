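"""Correlation-based feature clustering and representative selection.

Redundant informative features are grouped by hierarchical clustering of
the dissimilarity d = 1 - rho^2 (rho = Pearson correlation), so that
perfectly correlated *or* anticorrelated features are maximally similar.
Clustering is applied to features only, with complete linkage or a
Ward-type criterion applied directly to the d matrix. Cutting the tree
at level k yields k clusters; each cluster is represented by its most
informative member (smallest p-value, ties broken by larger IG, then
lexicographic feature ID).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .dataset import ExpressionDataset
from .relevance import RelevanceResult

__all__ = [
    "correlation_matrix",
    "dissimilarity",
    "hierarchical_cluster",
    "cut_and_represent",
    "top_n_features",
    "Dendrogram",
    "ClusterCut",
]

LINKAGES = ("complete", "ward")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over a fixed feature list."""

    feature_ids: list[str]
    merge_matrix: np.ndarray = field(repr=False)  # scipy linkage format

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class ClusterCut:
    """A k-cluster partition with one representative per cluster."""

    level: int
    assignment: dict[str, int]        # feature ID -> cluster index in 1..k
    representatives: dict[int, str]   # cluster index -> feature ID

    def __post_init__(self) -> None:
        clusters = set(self.assignment.values())
        if len(clusters) != self.level:
            raise ValueError(
                f"expected {self.level} non-empty clusters, got {len(clusters)}")
        for c, rep in self.representatives.items():
            if self.assignment.get(rep) != c:
                raise ValueError(f"representative {rep!r} not in its cluster {c}")

    @property
    def representative_features(self) -> list[str]:
        return [self.representatives[c] for c in sorted(self.representatives)]


def correlation_matrix(dataset: ExpressionDataset, features=None,
                       sample_idx=None) -> pd.DataFrame:
    """Pairwise Pearson correlation of features over the given samples.

    Correlations are computed on the provided (training) samples only;
    zero-variance features must have been filtered upstream.
    """
    features = list(features) if features is not None else dataset.feature_ids
    values = dataset.values[features]
    if sample_idx is not None:
        values = values.iloc[sample_idx]
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute correlations")
    arr = values.to_numpy()
    if np.any(arr.std(axis=0) == 0):
        bad = [f for f, s in zip(features, arr.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance features in correlation input: {bad[:5]}")
    rho = np.corrcoef(arr, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    return pd.DataFrame(rho, index=features, columns=features)


def dissimilarity(rho):
    """d = 1 - rho^2, elementwise; anticorrelation counts as similarity."""
    arr = np.asarray(rho, dtype=float) if not isinstance(rho, pd.DataFrame) else rho
    vals = arr.to_numpy() if isinstance(arr, pd.DataFrame) else arr
    if np.any(np.abs(vals) > 1 + 1e-12):
        raise ValueError("correlations must satisfy |rho| <= 1")
    d = 1.0 - np.clip(np.abs(vals), 0.0, 1.0) ** 2
    if isinstance(rho, pd.DataFrame):
        return pd.DataFrame(d, index=rho.index, columns=rho.columns)
    if np.isscalar(rho):
        return float(d)
    return d


def hierarchical_cluster(d_matrix: pd.DataFrame, method: str = "complete") -> Dendrogram:
    """Agglomerate features on a precomputed dissimilarity matrix.

    ``method="ward"`` applies the Ward-type (squared-height) update
    directly to d. Features are sorted lexicographically first so equal
    merge heights resolve deterministically by smallest member ID.
    """
    if method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {method!r}")
    if d_matrix.shape[0] < 2:
        raise ValueError("need at least 2 features to cluster")
    order = sorted(d_matrix.index.astype(str))
    d_sorted = d_matrix.loc[order, order]
    vals = d_sorted.to_numpy(dtype=float)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0
    condensed = squareform(vals, checks=False)
    merge = linkage(condensed, method=method)
    return Dendrogram(order, merge)


def cut_and_represent(dendrogram: Dendrogram, k: int,
                      relevance: RelevanceResult | pd.DataFrame) -> ClusterCut:
    """Cut into k clusters and pick the most informative member of each.

    The representative is the cluster member with the smallest p-value;
    ties go to the larger ``ig_max``, then the lexicographically
    smallest feature ID.
    """
    if not (1 <= k <= dendrogram.n_features):
        raise ValueError(
            f"k must be in [1, {dendrogram.n_features}], got {k}")
    table = relevance.table if isinstance(relevance, RelevanceResult) else relevance
    labels = cut_tree(dendrogram.merge_matrix, n_clusters=k).ravel()
    assignment = {f: int(c) + 1 for f, c in zip(dendrogram.feature_ids, labels)}
    reps: dict[int, str] = {}
    for c in sorted(set(assignment.values())):
        members = [f for f, cc in assignment.items() if cc == c]
        reps[c] = min(
            members,
            key=lambda f: (table.loc[f, "p_value"], -table.loc[f, "ig_max"], str(f)),
        )
    return ClusterCut(k, assignment, reps)


def top_n_features(relevance: RelevanceResult, n: int) -> list[str]:
    """The non-clustered baseline: first n relevant features by (p, -IG, ID)."""
    ranked = relevance.ranked()
    relevant = [f for f in ranked.index if ranked.loc[f, "relevant"]]
    if n > len(relevant):
        raise ValueError(f"requested top {n} but only {len(relevant)} relevant features")
    return relevant[:n]
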