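"""Disease dendrograms from specificity-score vectors.

Diseases are compared by the Euclidean distance between their score vectors
(over genes, TFs, or all TF-gene regulations), agglomerated with complete
linkage, and cut with an adaptive branch-pruning rule in the spirit of
dynamic tree cut: branches that attach well above their internal merge
heights become clusters, leaves peeled off along the way are reported as
singleton clusters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .datamodel import ClusterAssignment, Dendrogram, ScoreTable


def score_vectors(table: ScoreTable) -> pd.DataFrame:
    """Disease -> score vector matrix (features x diseases).

    Features with an undefined score in ANY disease are dropped for all
    diseases, keeping the pairwise distances consistent.
    """
    wide = table.score_matrix()
    return wide.dropna(axis=0, how="any")


def pairwise_score_distance(vectors: pd.DataFrame) -> pd.DataFrame:
    """Symmetric zero-diagonal Euclidean distance matrix between diseases.

    ``vectors`` holds one column per disease (features x diseases).
    """
    if vectors.shape[1] < 2:
        raise ValueError("need at least 2 diseases")
    x = vectors.to_numpy(dtype=float)
    diff = x[:, :, None] - x[:, None, :]
    d = np.sqrt((diff**2).sum(axis=0))
    return pd.DataFrame(d, index=vectors.columns, columns=vectors.columns)


def complete_linkage_dendrogram(dist: pd.DataFrame) -> Dendrogram:
    """Agglomerate with complete linkage (inter-cluster distance = max pair)."""
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if d.shape[0] < 2:
        raise ValueError("need at least 2 diseases")
    z = linkage(squareform(d, checks=False), method="complete")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(labels=list(dist.index), merges=merges)


def adaptive_prune(
    dend: Dendrogram,
    min_cluster_size: int = 2,
    gap_fraction: float = 0.25,
) -> ClusterAssignment:
    """Cut a dendrogram by recursive branch evaluation (dynamic-tree-cut style).

    Walking top-down, an internal branch is split when its merge height
    exceeds the mean of its descendant merge heights by more than
    ``gap_fraction`` x (global height range); a branch that is not split
    becomes one cluster.  Two-leaf branches are never split below
    themselves, and leaves peeled off at a split become singleton clusters
    (clusters below ``min_cluster_size`` are reported as singletons).
    """
    d = len(dend.labels)
    heights = np.array([h for _, _, h in dend.merges])
    h_range = float(heights.max() - heights.min()) if len(heights) else 0.0
    threshold = gap_fraction * h_range

    def descendant_heights(node: int) -> list[float]:
        if node < d:
            return []
        left, right, h = dend.merges[node - d]
        return descendant_heights(left) + descendant_heights(right) + [h]

    clusters: list[list[int]] = []

    def walk(node: int) -> None:
        if node < d:
            clusters.append([node])
            return
        left, right, h = dend.merges[node - d]
        internal = descendant_heights(left) + descendant_heights(right)
        # a cherry (no internal merges) is a cluster, never two singletons
        if internal and (h - float(np.mean(internal))) > threshold:
            walk(left)
            walk(right)
        else:
            clusters.append(dend.leaves_under(node))

    walk(2 * d - 2 if d > 1 else 0)

    assignment: dict[str, int] = {}
    cid = 0
    for members in clusters:
        if len(members) >= min_cluster_size:
            for m in members:
                assignment[dend.labels[m]] = cid
            cid += 1
        else:
            for m in members:  # singleton report
                assignment[dend.labels[m]] = cid
                cid += 1
    return ClusterAssignment(assignment=assignment)


def cluster_diseases(
    table: ScoreTable,
    min_cluster_size: int = 2,
    gap_fraction: float = 0.25,
) -> tuple[pd.DataFrame, Dendrogram, ClusterAssignment]:
    """Distance matrix, dendrogram and pruned assignment from a score table."""
    vectors = score_vectors(table)
    dist = pairwise_score_distance(vectors)
    dend = complete_linkage_dendrogram(dist)
    assign = adaptive_prune(dend, min_cluster_size, gap_fraction)
    return dist, dend, assign
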