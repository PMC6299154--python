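"""Per-purpose random substreams derived from one master seed.

Every stochastic stage draws from ``substream(master_seed, purpose)``, a
:class:`numpy.random.Generator` keyed by a named purpose.  Substreams are
statistically independent (numpy ``SeedSequence`` spawn keys), so any stage
can be regenerated on its own without replaying the stages before it.
"""

from __future__ import annotations

import numpy as np

# Fixed purpose -> spawn-key registry. Never renumber: doing so silently
# changes every downstream dataset generated from a given master seed.
_PURPOSES = {
    "host_tree": 0,
    "root_abundance": 1,
    "brownian": 2,
    "host_noise": 3,
    "multinomial": 4,
    "contig_lengths": 5,
    "rarefaction": 6,
    "null_topologies": 7,
    "label_shuffle": 8,
}


def substream(seed: int, purpose: str) -> np.random.Generator:
    """Return the dedicated random generator for one named purpose."""
    if purpose not in _PURPOSES:
        raise KeyError(f"unknown random substream purpose: {purpose!r}")
    seq = np.random.SeedSequence(int(seed), spawn_key=(_PURPOSES[purpose],))
    return np.random.default_rng(seq)


def substream_seed(seed: int, purpose: str) -> int:
    """A derived 31-bit integer seed for stages that take plain int seeds."""
    rng = substream(seed, purpose)
    return int(rng.integers(0, 2**31 - 1))
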