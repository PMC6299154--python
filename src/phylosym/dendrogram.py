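"""UPGMA clustering, cophenetic distances, and consensus dendrograms.

UPGMA (unweighted pair group method with arithmetic mean) repeatedly merges
the two closest clusters; the distance between clusters is the arithmetic
mean of all between-cluster leaf pairs (maintained by size-weighted
averaging), and a merge at distance d places the new node at height d/2, so
the output dendrogram is ultrametric.  Ties are broken on the
lexicographically smallest pair of sorted cluster-label tuples, which makes
the result independent of input order.

A set of replicate dendrograms (one per rarefaction) is combined into a
consensus by averaging their cophenetic matrices elementwise and running
UPGMA on the mean matrix — deterministic, and always a well-formed
ultrametric tree.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = ["upgma", "cophenetic", "consensus_dendrogram"]


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Build the UPGMA dendrogram of a distance matrix.

    Merge heights are encoded as branch lengths (leaves sit at height 0), so
    the tip-to-tip path distance equals the cophenetic distance
    2 x height(LCA).

    Raises ``ValueError`` on negative entries; asymmetry is rejected by the
    ``DistanceMatrix`` type itself.
    """
    if not isinstance(dist, DistanceMatrix):
        dist = DistanceMatrix(dist)  # validates symmetry / zero diagonal
    if (dist.data < 0).any():
        raise ValueError("distance matrix entries must be non-negative")
    n = dist.shape[0]
    if n < 2:
        raise ValueError("UPGMA needs at least 2 samples")

    # cluster id -> (sorted leaf-label tuple, size, height, subtree)
    labels = {i: (str(dist.ids[i]),) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: TreeNode(name=str(dist.ids[i])) for i in range(n)}
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n

    while len(nodes) > 1:
        # deterministic argmin: distance, then lexicographic label-tuple pair
        best = min(
            d.items(),
            key=lambda kv: (kv[1], *sorted((labels[min(kv[0])], labels[max(kv[0])]))),
        )
        (pair, dmin) = best
        i, j = sorted(pair, key=lambda c: labels[c])
        h = dmin / 2.0
        child_i, child_j = nodes.pop(i), nodes.pop(j)
        child_i.length = h - heights[i]
        child_j.length = h - heights[j]
        parent = TreeNode(children=[child_i, child_j])
        nodes[next_id] = parent
        labels[next_id] = tuple(sorted(labels[i] + labels[j]))
        sizes[next_id] = sizes[i] + sizes[j]
        heights[next_id] = h
        del d[pair]
        for k in list(nodes):
            if k == next_id:
                continue
            dik = d.pop(frozenset((i, k)))
            djk = d.pop(frozenset((j, k)))
            d[frozenset((next_id, k))] = (sizes[i] * dik + sizes[j] * djk) / sizes[next_id]
        next_id += 1

    root = nodes.popitem()[1]
    root.length = None
    return root


def _leaf_depths(tree: TreeNode) -> dict:
    depths = {}
    for tip in tree.tips():
        depth = 0.0
        node = tip
        while node.parent is not None:
            if node.length is None:
                raise ValueError("cophenetic requires branch lengths on all non-root nodes")
            depth += node.length
            node = node.parent
        depths[tip.name] = depth
    return depths


def cophenetic(tree: TreeNode, rtol: float = 1e-8) -> DistanceMatrix:
    """Cophenetic distances of an ultrametric dendrogram.

    Entry (i, j) is twice the height of the lowest common ancestor of leaves
    i and j, which for an ultrametric tree equals the tip-to-tip path
    length.  Raises if branch lengths are missing or leaf depths disagree
    beyond ``rtol`` (the tree is not a dendrogram).
    """
    depths = _leaf_depths(tree)
    vals = np.array(list(depths.values()))
    if len(vals) < 2:
        raise ValueError("cophenetic needs at least 2 leaves")
    span = vals.max() - vals.min()
    if span > rtol * max(vals.max(), 1.0):
        raise ValueError("tree is not ultrametric; cophenetic heights are ill-defined")
    dm = tree.tip_tip_distances()
    order = sorted(dm.ids)
    return dm.filter(order)


def consensus_dendrogram(replicate_dists: Sequence[DistanceMatrix]) -> TreeNode:
    """Consensus dendrogram across replicate distance matrices.

    Each replicate matrix is clustered with UPGMA; the replicate trees'
    cophenetic matrices are averaged elementwise and the mean matrix is
    clustered again.  With a single replicate this reduces to that
    replicate's own UPGMA tree.
    """
    if len(replicate_dists) < 1:
        raise ValueError("need at least one replicate distance matrix")
    id_sets = [frozenset(dm.ids) for dm in replicate_dists]
    if len(set(id_sets)) != 1:
        raise ValueError("replicate distance matrices have mismatched sample sets")
    order = sorted(replicate_dists[0].ids)
    mats = [cophenetic(upgma(dm)).filter(order).data for dm in replicate_dists]
    mean = np.mean(mats, axis=0)
    return upgma(DistanceMatrix(mean, ids=order))
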