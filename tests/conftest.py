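"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately re-derive quantities from first
principles (nested-tuple topology enumeration, by-hand cluster collection,
all-matchings search) so the package implementations are checked against an
independent route, not against themselves.
"""

from __future__ import annotations

from itertools import combinations, permutations

import pandas as pd
import pytest

from phylosym.io import COVERAGE_COLUMNS, parse_newick


# ---------------------------------------------------------------------------
# nested-tuple topology oracle (independent of phylosym.congruence)


def enumerate_topologies(labels):
    """All rooted binary labeled topologies on ``labels`` as nested tuples."""
    labels = tuple(labels)
    if len(labels) == 1:
        return [labels[0]]
    out = []
    rest = labels[1:]
    # the subtree containing labels[0] determines an unordered root split
    for k in range(0, len(rest)):
        for left_rest in combinations(rest, k):
            left = (labels[0],) + left_rest
            right = tuple(x for x in rest if x not in left_rest)
            if not right:
                continue
            for lt in enumerate_topologies(left):
                for rt in enumerate_topologies(right):
                    out.append((lt, rt))
    return out


def topology_clusters(topo):
    """Nontrivial clusters of a nested-tuple topology, by direct recursion."""
    clusters = []

    def rec(node):
        if not isinstance(node, tuple):
            return frozenset([node])
        leaves = frozenset()
        for child in node:
            leaves |= rec(child)
        clusters.append(leaves)
        return leaves

    all_leaves = rec(topo)
    n = len(all_leaves)
    return frozenset(c for c in clusters if 2 <= len(c) <= n - 1)


def brute_force_matching_cluster(clusters_a, clusters_b):
    """Minimum-cost perfect matching by exhaustive search over permutations."""
    a, b = list(clusters_a), list(clusters_b)
    m = max(len(a), len(b))
    a += [frozenset()] * (m - len(a))
    b += [frozenset()] * (m - len(b))
    best = None
    for perm in permutations(range(m)):
        cost = sum(len(a[i] ^ b[j]) for i, j in enumerate(perm))
        if best is None or cost < best:
            best = cost
    return best if best is not None else 0


def topology_to_newick(topo):
    if not isinstance(topo, tuple):
        return str(topo)
    return "(" + ",".join(topology_to_newick(c) for c in topo) + ")"


def topology_to_tree(topo):
    return parse_newick(topology_to_newick(topo) + ";")


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def caterpillar():
    """The 5-leaf pectinate topology used throughout the worked examples."""
    return parse_newick("((((A,B),C),D),E);")


@pytest.fixture
def power_host_tree():
    """Fixed ultrametric 5-host phylogeny for the synthetic power studies."""
    return parse_newick("((((H1:0.1,H2:0.1):0.1,H3:0.2):0.1,H4:0.3):0.1,H5:0.4);")


@pytest.fixture
def small_coverage_table():
    """Three samples, four contigs, hand-set breadths and depths."""
    rows = [
        # sample, contig, length, reads, bases_covered, mean_depth
        ("S1", "c1", 1000, 500, 900, 50.0),
        ("S1", "c2", 2000, 100, 1800, 5.0),
        ("S2", "c1", 1000, 400, 800, 40.0),
        ("S2", "c3", 1500, 300, 1400, 20.0),
        ("S3", "c1", 1000, 200, 950, 20.0),
        ("S3", "c4", 800, 50, 100, 6.3),
    ]
    return pd.DataFrame(rows, columns=COVERAGE_COLUMNS)
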