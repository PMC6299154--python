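"""Synthetic host trees and virome communities with tunable phylogenetic signal.

The study design being emulated is a handful of host lines, one shotgun
virome each, summarised as per-contig read counts and coverage.  Real data
of that shape cannot separate "the virome tracks the host phylogeny" from
"the virome assembled stochastically", so this module provides a generative
model in which the amount of host-tree structure is a knob:

* the host phylogeny is a Yule (pure-birth) tree;
* each contig's log-abundance starts at a root draw and evolves along the
  tree as Brownian motion with per-branch variance ``signal_sd**2 * branch
  length`` (phylogenetic signal), plus independent per-host noise with
  standard deviation ``noise_sd`` (non-phylogenetic ecology);
* each host's read counts are one multinomial draw of ``sequencing_depth``
  reads with probabilities proportional to the exponentiated log-abundances;
* coverage summaries use the Lander-Waterman approximation: at mean depth d
  the expected breadth is 1 - exp(-d).

``signal_sd / noise_sd`` is the single interpretable signal-to-noise ratio:
at 0 the hosts are exchangeable (the stochastic-assembly null); large values
make the between-host dissimilarity structure mirror the host tree.

All randomness derives from one master seed through named substreams
(:mod:`phylosym._seeds`), so each stage regenerates independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skbio import TreeNode

from phylosym._seeds import substream
from phylosym.io import COVERAGE_COLUMNS

__all__ = [
    "SyntheticConfig",
    "simulate_host_tree",
    "simulate_virome_counts",
    "simulate_coverage_table",
    "make_core_fixture",
]

# sd of the root log-abundance draw: baseline heterogeneity between contigs
_ROOT_SD = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic virome generator.

    Defaults mirror the emulated study design: 5 host samples, ~1,000 viral
    contigs, 2 x 100 bp short reads, and a per-sample depth comfortably above
    the 16,400-count rarefaction depth used downstream.
    """

    n_hosts: int = 5
    n_contigs: int = 1000
    signal_sd: float = 1.0
    noise_sd: float = 0.5
    sequencing_depth: int = 50_000
    read_length: int = 100
    contig_length_range: Tuple[int, int] = (500, 40_000)
    seed: int = 0

    def __post_init__(self):
        if self.n_hosts < 2:
            raise ValueError("n_hosts must be >= 2")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")
        if self.signal_sd < 0 or self.noise_sd < 0:
            raise ValueError("signal_sd and noise_sd must be non-negative")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        lo, hi = self.contig_length_range
        if lo < 1 or hi < lo:
            raise ValueError("contig_length_range must satisfy 1 <= lo <= hi")


def simulate_host_tree(n_hosts: int, seed: int) -> TreeNode:
    """Simulate a rooted binary host phylogeny under a Yule process.

    Lineages split at rate 1; after the n-th lineage appears the tree is
    extended by one more exponential waiting time so every pendant branch is
    strictly positive.  Leaves are labeled ``H1..Hn``.  Deterministic for a
    fixed seed.
    """
    if n_hosts < 2:
        raise ValueError("n_hosts must be >= 2")
    rng = substream(seed, "host_tree")

    root = TreeNode()
    birth: Dict[int, float] = {}
    a, b = TreeNode(), TreeNode()
    root.extend([a, b])
    birth[id(a)] = birth[id(b)] = 0.0
    leaves = [a, b]
    t = 0.0
    while len(leaves) < n_hosts:
        t += rng.exponential(1.0 / len(leaves))
        i = int(rng.integers(len(leaves)))
        v = leaves[i]
        c1, c2 = TreeNode(), TreeNode()
        v.extend([c1, c2])
        v.length = t - birth[id(v)]
        birth[id(c1)] = birth[id(c2)] = t
        leaves[i] = c1
        leaves.append(c2)
    t_final = t + rng.exponential(1.0 / n_hosts)
    for k, leaf in enumerate(leaves, start=1):
        leaf.length = t_final - birth[id(leaf)]
        leaf.name = f"H{k}"
    root.length = None
    return root


def simulate_virome_counts(tree: TreeNode, cfg: SyntheticConfig) -> pd.DataFrame:
    """Simulate a contig-by-host count matrix with tree-structured signal.

    Per contig, a root log-abundance ~ Normal(0, 1) evolves down ``tree`` as
    Brownian motion (variance ``cfg.signal_sd**2`` per unit branch length);
    independent Normal(0, ``cfg.noise_sd``) noise is added per host; counts
    are a multinomial draw of ``cfg.sequencing_depth`` reads per host over
    softmax-transformed log-abundances.  Every column sums exactly to the
    sequencing depth.
    """
    leaf_names = [tip.name for tip in tree.tips()]
    if len(leaf_names) != len(set(leaf_names)) or any(n is None for n in leaf_names):
        raise ValueError("host tree leaves must carry unique sample labels")
    if len(leaf_names) != cfg.n_hosts:
        raise ValueError(
            f"host tree has {len(leaf_names)} leaves but cfg.n_hosts={cfg.n_hosts}"
        )

    rng_root = substream(cfg.seed, "root_abundance")
    rng_bm = substream(cfg.seed, "brownian")
    rng_noise = substream(cfg.seed, "host_noise")
    rng_counts = substream(cfg.seed, "multinomial")

    values: Dict[int, np.ndarray] = {id(tree): rng_root.normal(0.0, _ROOT_SD, cfg.n_contigs)}
    leaf_logs: Dict[str, np.ndarray] = {}
    for node in tree.preorder(include_self=False):
        bl = node.length if node.length is not None else 0.0
        if bl < 0:
            raise ValueError("host tree branch lengths must be non-negative")
        step_sd = cfg.signal_sd * np.sqrt(bl)
        val = values[id(node.parent)] + rng_bm.normal(0.0, 1.0, cfg.n_contigs) * step_sd
        if node.is_tip():
            leaf_logs[node.name] = val
        else:
            values[id(node)] = val

    contigs = [f"c{i + 1:05d}" for i in range(cfg.n_contigs)]
    counts = np.empty((cfg.n_contigs, len(leaf_names)), dtype=np.int64)
    for j, name in enumerate(leaf_names):
        logp = leaf_logs[name] + rng_noise.normal(0.0, cfg.noise_sd, cfg.n_contigs)
        logp -= logp.max()
        p = np.exp(logp)
        p /= p.sum()
        counts[:, j] = rng_counts.multinomial(cfg.sequencing_depth, p)
    out = pd.DataFrame(counts, index=contigs, columns=leaf_names)
    out.attrs["mode"] = "counts"
    return out


def simulate_coverage_table(
    abundance: pd.DataFrame,
    cfg: SyntheticConfig,
    lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Deterministic coverage summaries for a count matrix.

    Contig lengths are drawn uniformly on ``cfg.contig_length_range`` (from
    the master seed's dedicated substream) unless supplied.  Mean depth is
    ``reads * read_length / length``; expected breadth follows the
    Lander-Waterman approximation ``1 - exp(-depth)``; bases covered is the
    rounded expected breadth times the length.  Deterministic given the
    abundances and lengths.
    """
    if (abundance.to_numpy() < 0).any():
        raise ValueError("abundance counts must be non-negative")
    contigs = list(abundance.index)
    if lengths is None:
        rng = substream(cfg.seed, "contig_lengths")
        lo, hi = cfg.contig_length_range
        drawn = rng.integers(lo, hi + 1, size=len(contigs))
        lengths = dict(zip(contigs, (int(x) for x in drawn)))
    if any(lengths[c] <= 0 for c in contigs):
        raise ValueError("contig lengths must be positive")

    records = []
    for sample in abundance.columns:
        col = abundance[sample]
        for contig in contigs:
            reads = int(col[contig])
            length = int(lengths[contig])
            depth = reads * cfg.read_length / length
            breadth = 1.0 - np.exp(-depth)
            records.append(
                (sample, contig, length, reads, int(round(breadth * length)), depth)
            )
    return pd.DataFrame(records, columns=COVERAGE_COLUMNS)


def make_core_fixture(
    present: Mapping[str, Iterable[str]],
    absent: Optional[Mapping[str, Iterable[str]]] = None,
    contig_length: int = 1000,
) -> Tuple[pd.DataFrame, dict]:
    """Coverage table with known presence design plus its ground-truth partition.

    ``present`` lists, per sample, the contigs that must be called present
    under the 75%-breadth rule; every other contig in the design universe is
    absent for that sample.  ``absent`` may add contigs that appear in no
    sample at all (or assert absences explicitly; listing a contig as both
    present and absent for one sample is contradictory and raises).

    Breadths are placed strictly on either side of 0.75 (0.95 vs 0.40), and
    depths are high enough that the default contig filters keep everything.
    Returns ``(coverage_table, expected)`` where ``expected`` holds the
    ground-truth ``regions`` (sample subset -> contig set), ``core`` set and
    region ``sizes``.
    """
    if len(present) < 2:
        raise ValueError("core fixture needs at least 2 samples")
    present_sets = {s: frozenset(v) for s, v in present.items()}
    absent_sets = {s: frozenset(v) for s, v in (absent or {}).items()}
    for s, contigs in absent_sets.items():
        if s in present_sets and present_sets[s] & contigs:
            clash = sorted(present_sets[s] & contigs)
            raise ValueError(f"contradictory design for sample {s}: {clash}")

    universe = sorted(set().union(*present_sets.values(), *absent_sets.values() or [set()]))
    samples = sorted(present_sets)
    records = []
    for s in samples:
        for c in universe:
            breadth = 0.95 if c in present_sets[s] else 0.40
            records.append((s, c, contig_length, 500, int(round(breadth * contig_length)), 10.0))
    table = pd.DataFrame(records, columns=COVERAGE_COLUMNS)

    membership: Dict[frozenset, set] = {}
    for c in universe:
        subset = frozenset(s for s in samples if c in present_sets[s])
        if subset:
            membership.setdefault(subset, set()).add(c)
    regions = {k: frozenset(v) for k, v in membership.items()}
    core = regions.get(frozenset(samples), frozenset())
    expected = {
        "regions": regions,
        "core": core,
        "sizes": {k: len(v) for k, v in regions.items()},
    }
    return table, expected
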