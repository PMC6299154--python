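"""Topological congruence between a host phylogeny and a community dendrogram.

The phylosymbiosis test asks whether a beta-diversity dendrogram of
host-associated communities parallels the host phylogeny more than chance
would allow.  Congruence is measured on rooted tree *topologies* through
their cluster sets (for every internal node except the root, the set of leaf
labels below it):

rooted Robinson-Foulds (RF)
    The size of the symmetric difference of the two cluster sets.
rooted matching-cluster (MC)
    The minimum total cost of a perfect matching between the two cluster
    lists (padded with empty sets), where pairing clusters X and Y costs
    |X Δ Y|.  MC refines RF: clusters that almost agree cost little instead
    of a flat 2.

Significance comes from a Monte Carlo null of random bifurcating topologies
on the same leaf labels — "stochastic community assembly".  Two generators
are provided: ``uniform`` (uniform over all (2n-3)!! labeled rooted binary
topologies, via sequential random edge attachment) and ``yule`` (random
labeled histories, via repeated splitting of a uniformly chosen leaf).  The
p-value is the fraction of null topologies at least as close to the host
tree as the observed dendrogram.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from skbio import TreeNode

__all__ = [
    "clusters",
    "robinson_foulds_rooted",
    "matching_cluster",
    "random_topology",
    "congruence_test",
    "CongruenceResult",
]


# ---------------------------------------------------------------------------
# cluster extraction


def _tip_names(tree: TreeNode) -> List[str]:
    names = [t.name for t in tree.tips()]
    if any(n is None for n in names):
        raise ValueError("all leaves must be labeled")
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf labels in tree")
    return names


def clusters(tree: TreeNode) -> FrozenSet[FrozenSet[str]]:
    """Nontrivial clusters of a rooted tree.

    One frozenset of leaf labels per internal node other than the root;
    singletons and the full leaf set are excluded.  For a binary rooted tree
    on n leaves this yields exactly n-2 clusters.
    """
    names = _tip_names(tree)
    n = len(names)
    out = set()
    for node in tree.non_tips(include_self=False):
        leaves = frozenset(t.name for t in node.tips())
        if 2 <= len(leaves) <= n - 1:
            out.add(leaves)
    return frozenset(out)


def _cluster_masks(tree: TreeNode, bit: Dict[str, int]) -> List[int]:
    """Clusters as leaf-set bitmasks under a shared label -> bit index."""
    n = len(bit)
    masks = []
    for node in tree.non_tips(include_self=False):
        m = 0
        for t in node.tips():
            m |= 1 << bit[t.name]
        if 2 <= m.bit_count() <= n - 1:
            masks.append(m)
    return masks


def _check_same_leaves(t1: TreeNode, t2: TreeNode) -> List[str]:
    n1, n2 = _tip_names(t1), _tip_names(t2)
    if set(n1) != set(n2):
        raise ValueError("trees have different leaf label sets")
    return sorted(n1)


# ---------------------------------------------------------------------------
# distances


def robinson_foulds_rooted(t1: TreeNode, t2: TreeNode) -> int:
    """Rooted Robinson-Foulds distance: |C1 Δ C2| over nontrivial clusters."""
    _check_same_leaves(t1, t2)
    return len(clusters(t1) ^ clusters(t2))


def _rf_masks(m1: FrozenSet[int], m2: FrozenSet[int]) -> int:
    return len(m1 ^ m2)


def _mc_masks(m1: Sequence[int], m2: Sequence[int]) -> int:
    """Matching-cluster distance on bitmask cluster lists (empty-set padding)."""
    m = max(len(m1), len(m2))
    if m == 0:
        return 0
    a = list(m1) + [0] * (m - len(m1))
    b = list(m2) + [0] * (m - len(m2))
    if m <= 4:
        best = None
        for perm in permutations(range(m)):
            tot = 0
            for i, j in enumerate(perm):
                tot += (a[i] ^ b[j]).bit_count()
                if best is not None and tot >= best:
                    break
            else:
                best = tot if best is None else min(best, tot)
        return best
    cost = np.empty((m, m), dtype=np.int64)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            cost[i, j] = (x ^ y).bit_count()
    ri, cj = linear_sum_assignment(cost)
    return int(cost[ri, cj].sum())


def matching_cluster(t1: TreeNode, t2: TreeNode) -> int:
    """Rooted matching-cluster distance (minimum-cost cluster matching)."""
    labels = _check_same_leaves(t1, t2)
    bit = {name: i for i, name in enumerate(labels)}
    return _mc_masks(_cluster_masks(t1, bit), _cluster_masks(t2, bit))


# ---------------------------------------------------------------------------
# random topologies


class _BNode:
    __slots__ = ("children", "leaf", "parent")

    def __init__(self, leaf: Optional[int] = None):
        self.children: List["_BNode"] = []
        self.leaf = leaf
        self.parent: Optional["_BNode"] = None


def _attach(parent: _BNode, child: _BNode) -> None:
    parent.children.append(child)
    child.parent = parent


def _sample_uniform(order: Sequence[int], rng: np.random.Generator) -> _BNode:
    """Sequential random attachment: uniform over labeled rooted binary trees.

    Each new leaf is attached to an edge chosen uniformly among all edges of
    the current tree plus the root edge; a k-leaf tree offers 2k-1
    attachment points, giving each of the (2n-3)!! topologies equal mass.
    """
    a, b = _BNode(order[0]), _BNode(order[1])
    root = _BNode()
    _attach(root, a)
    _attach(root, b)
    nodes = [a, b, root]
    for label in order[2:]:
        v = nodes[int(rng.integers(len(nodes)))]
        leaf = _BNode(label)
        u = _BNode()
        if v.parent is None:
            root = u
        else:
            v.parent.children[v.parent.children.index(v)] = u
            u.parent = v.parent
        _attach(u, v)
        _attach(u, leaf)
        nodes.append(leaf)
        nodes.append(u)
    return root


def _sample_yule(order: Sequence[int], rng: np.random.Generator) -> _BNode:
    """Yule / random-labeled-history sampling: split a uniform leaf each step."""
    a, b = _BNode(order[0]), _BNode(order[1])
    root = _BNode()
    _attach(root, a)
    _attach(root, b)
    leaves = [a, b]
    for label in order[2:]:
        i = int(rng.integers(len(leaves)))
        v = leaves[i]
        c1, c2 = _BNode(v.leaf), _BNode(label)
        v.leaf = None
        _attach(v, c1)
        _attach(v, c2)
        leaves[i] = c1
        leaves.append(c2)
    return root


_SCHEMES = {"uniform": _sample_uniform, "yule": _sample_yule}


def _masks_of(root: _BNode, n: int) -> List[int]:
    """Nontrivial cluster bitmasks of a sampled binary topology."""
    masks: List[int] = []

    def rec(node: _BNode) -> int:
        if node.leaf is not None:
            return 1 << node.leaf
        m = 0
        for c in node.children:
            m |= rec(c)
        if node is not root:
            masks.append(m)
        return m

    rec(root)
    return masks


def _sample_null_masks(n: int, scheme: str, rng: np.random.Generator) -> List[int]:
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown null scheme {scheme!r}; choose 'uniform' or 'yule'")
    order = [int(x) for x in rng.permutation(n)]
    return _masks_of(_SCHEMES[scheme](order, rng), n)


def _bnode_to_treenode(node: _BNode, labels: Sequence[str]) -> TreeNode:
    if node.leaf is not None:
        return TreeNode(name=labels[node.leaf], length=1.0)
    children = [_bnode_to_treenode(c, labels) for c in node.children]
    out = TreeNode(children=children)
    out.length = 1.0
    return out


def random_topology(labels: Sequence[str], scheme: str = "uniform", seed: int = 0) -> TreeNode:
    """Sample one random rooted bifurcating topology on ``labels``.

    ``uniform`` draws uniformly over all (2n-3)!! labeled rooted binary
    topologies; ``yule`` draws uniformly over labeled histories.  Leaf label
    order is shuffled from the seed, so both schemes are exchangeable in the
    labels.  Branch lengths are set to 1 (topology is what matters here).
    """
    labels = list(labels)
    if len(labels) < 2 or len(set(labels)) != len(labels):
        raise ValueError("need at least 2 unique labels")
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown null scheme {scheme!r}; choose 'uniform' or 'yule'")
    rng = np.random.default_rng(seed)
    order = [int(x) for x in rng.permutation(len(labels))]
    root = _SCHEMES[scheme](order, rng)
    tree = _bnode_to_treenode(root, labels)
    tree.length = None
    return tree


# ---------------------------------------------------------------------------
# Monte Carlo congruence test


@dataclass(frozen=True)
class CongruenceResult:
    """Observed tree distances, Monte Carlo p-values and null summaries.

    ``p_rf``/``p_mc`` are the fractions of null topologies whose distance to
    the host tree is <= the observed distance.  When no null tree comes that
    close the p-value is reported as the upper bound 1/n_null and the
    corresponding ``*_upper_bound`` flag is set (a Monte Carlo p-value is
    never exactly zero).  ``rf_normalized``/``mc_normalized`` divide the
    observed distance by the maximum distance seen in the null sample (0/0
    defined as 0).
    """

    n_leaves: int
    n_null: int
    scheme: str
    seed: int
    metric: str
    rf: Optional[int] = None
    mc: Optional[int] = None
    rf_normalized: Optional[float] = None
    mc_normalized: Optional[float] = None
    p_rf: Optional[float] = None
    p_mc: Optional[float] = None
    rf_le_count: Optional[int] = None
    mc_le_count: Optional[int] = None
    p_rf_upper_bound: bool = False
    p_mc_upper_bound: bool = False
    null_rf_histogram: Dict[int, int] = field(default_factory=dict)
    null_mc_histogram: Dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_leaves": self.n_leaves,
            "n_null": self.n_null,
            "scheme": self.scheme,
            "seed": self.seed,
            "metric": self.metric,
            "rf": self.rf,
            "mc": self.mc,
            "rf_normalized": self.rf_normalized,
            "mc_normalized": self.mc_normalized,
            "p_rf": self.p_rf,
            "p_mc": self.p_mc,
            "rf_le_count": self.rf_le_count,
            "mc_le_count": self.mc_le_count,
            "p_rf_upper_bound": self.p_rf_upper_bound,
            "p_mc_upper_bound": self.p_mc_upper_bound,
            "null_rf_histogram": {str(k): v for k, v in sorted(self.null_rf_histogram.items())},
            "null_mc_histogram": {str(k): v for k, v in sorted(self.null_mc_histogram.items())},
        }


def congruence_test(
    host: TreeNode,
    dendro: TreeNode,
    n_null: int = 100_000,
    metric: str = "both",
    scheme: str = "uniform",
    seed: int = 0,
) -> CongruenceResult:
    """Monte Carlo test of topological congruence between two rooted trees.

    Computes the observed rooted RF and/or matching-cluster distance between
    ``host`` and ``dendro``, then compares against ``n_null`` random
    bifurcating topologies on the same leaf labels (both metrics are scored
    on the *same* null sample when ``metric='both'``).  Multifurcating
    inputs are accepted; the null trees are always bifurcating.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if metric not in ("rf", "mc", "both"):
        raise ValueError("metric must be 'rf', 'mc', or 'both'")
    labels = _check_same_leaves(host, dendro)
    n = len(labels)
    if n < 3:
        raise ValueError("congruence test needs at least 3 leaves")
    bit = {name: i for i, name in enumerate(labels)}

    host_masks = _cluster_masks(host, bit)
    dendro_masks = _cluster_masks(dendro, bit)
    host_set = frozenset(host_masks)

    want_rf = metric in ("rf", "both")
    want_mc = metric in ("mc", "both")
    obs_rf = _rf_masks(host_set, frozenset(dendro_masks)) if want_rf else None
    obs_mc = _mc_masks(host_masks, dendro_masks) if want_mc else None

    rng = np.random.default_rng(seed)
    rf_hist: Counter = Counter()
    mc_hist: Counter = Counter()
    rf_le = mc_le = 0
    for _ in range(n_null):
        null_masks = _sample_null_masks(n, scheme, rng)
        if want_rf:
            d = _rf_masks(host_set, frozenset(null_masks))
            rf_hist[d] += 1
            if d <= obs_rf:
                rf_le += 1
        if want_mc:
            d = _mc_masks(host_masks, null_masks)
            mc_hist[d] += 1
            if d <= obs_mc:
                mc_le += 1

    def finalize(obs, le, hist):
        if obs is None:
            return None, None, None, False
        upper = le == 0
        p = (1 if upper else le) / n_null
        dmax = max(hist)
        norm = 0.0 if obs == 0 and dmax == 0 else obs / dmax
        return p, le, norm, upper

    p_rf, rf_le_c, rf_norm, rf_up = finalize(obs_rf, rf_le, rf_hist) if want_rf else (None, None, None, False)
    p_mc, mc_le_c, mc_norm, mc_up = finalize(obs_mc, mc_le, mc_hist) if want_mc else (None, None, None, False)

    return CongruenceResult(
        n_leaves=n,
        n_null=n_null,
        scheme=scheme,
        seed=int(seed),
        metric=metric,
        rf=obs_rf,
        mc=obs_mc,
        rf_normalized=rf_norm,
        mc_normalized=mc_norm,
        p_rf=p_rf,
        p_mc=p_mc,
        rf_le_count=rf_le_c,
        mc_le_count=mc_le_c,
        p_rf_upper_bound=rf_up,
        p_mc_upper_bound=mc_up,
        null_rf_histogram=dict(rf_hist),
        null_mc_histogram=dict(mc_hist),
    )
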