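"""Reduce a pathway collection to its most distinct members.

Overlapping pathways (common in MSigDB-style collections) make grouped
penalties redundant; before group-lasso fitting the collection is cut to
the ``n_select`` most distinct sets via average-linkage hierarchical
clustering on the Jaccard distance between gene memberships, keeping one
medoid per cluster.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .containers import GeneSetCollection

__all__ = ["pathway_distance_matrix", "select_distinct_pathways"]


def pathway_distance_matrix(sets: GeneSetCollection) -> np.ndarray:
    """Symmetric Jaccard distance matrix on gene membership,
    ``d(A,B) = 1 - |A & B| / |A | B|``."""
    names = sets.names
    if len(names) < 2:
        raise ValueError("need >=2 gene sets for a distance matrix")
    members = [sets[n] for n in names]
    for name, m in zip(names, members):
        if not m:
            raise ValueError(f"gene set {name!r} is empty")
    k = len(names)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            inter = len(members[i] & members[j])
            union = len(members[i] | members[j])
            dist[i, j] = dist[j, i] = 1.0 - inter / union
    return dist


def select_distinct_pathways(sets: GeneSetCollection, n_select: int = 100) -> GeneSetCollection:
    """Pick the ``n_select`` most distinct pathways.

    Collections at or below ``n_select`` are returned unchanged.  Otherwise
    the Jaccard distance matrix is clustered (average linkage), the tree is
    cut into exactly ``n_select`` clusters, and each cluster is represented
    by its medoid — the member with the smallest summed distance to the
    rest of its cluster, ties broken by lexicographic name.  Output sets
    are originals (never merged) in their original collection order.
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    names = sets.names
    if len(names) <= n_select:
        return sets
    dist = pathway_distance_matrix(sets)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = cut_tree(z, n_clusters=n_select).ravel()
    chosen: list[str] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        within = dist[np.ix_(idx, idx)].sum(axis=1)
        best = min(zip(within, (names[i] for i in idx)))[1]
        chosen.append(best)
    keep = set(chosen)
    return sets.subset([n for n in names if n in keep])
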