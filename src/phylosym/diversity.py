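"""Rarefaction and beta-diversity distances (Bray-Curtis, binary Jaccard).

Rarefaction subsamples each sample's reads to a common depth *without
replacement* (multivariate hypergeometric), the standard way to normalise
unequal sequencing effort before comparing communities.  Bray-Curtis works
on (rarefied) counts; binary Jaccard works on presence/absence.
"""

from __future__ import annotations

from typing import List, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from phylosym.coverage import PresenceMatrix

__all__ = ["rarefy", "rarefaction_set", "bray_curtis", "binary_jaccard"]


def _as_count_array(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    return np.round(arr).astype(np.int64)


def rarefy(counts: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every sample column to exactly ``depth`` reads.

    Each column is a multivariate-hypergeometric draw of ``depth`` reads from
    that sample's read pool, so rarefied counts never exceed the originals
    and each column sums to ``depth`` exactly.

    Raises
    ------
    ValueError
        If any sample's total is below ``depth`` (the offending sample is
        named), or counts are negative/non-integer.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    arr = _as_count_array(counts)
    totals = arr.sum(axis=0)
    short = [str(s) for s, t in zip(counts.columns, totals) if t < depth]
    if short:
        raise ValueError(
            f"insufficient depth: sample(s) {', '.join(short)} have fewer than "
            f"{depth} total counts"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(arr[:, j], depth)
    res = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    res.attrs["mode"] = "counts"
    res.attrs["rarefaction_depth"] = int(depth)
    return res


def rarefaction_set(
    counts: pd.DataFrame, depth: int, n_replicates: int, seed: int
) -> List[pd.DataFrame]:
    """``n_replicates`` independent rarefactions; replicate r uses seed+r."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [rarefy(counts, depth, seed + r) for r in range(n_replicates)]


def _check_matrix(x: np.ndarray) -> None:
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")


def bray_curtis(counts: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    BC(u, v) = sum_i |u_i - v_i| / sum_i (u_i + v_i).  Undefined for a pair
    of all-zero samples, which raises.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    _check_matrix(arr)
    zero_cols = [str(s) for s, t in zip(counts.columns, arr.sum(axis=0)) if t == 0]
    if len(zero_cols) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero samples: {', '.join(zero_cols)}"
        )
    d = squareform(pdist(arr.T, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(c) for c in counts.columns])


def binary_jaccard(presence: Union[PresenceMatrix, pd.DataFrame]) -> DistanceMatrix:
    """Binary Jaccard distance 1 - |U∩V| / |U∪V| between sample presence sets.

    Accepts a :class:`PresenceMatrix` or any contig-by-sample matrix, which
    is binarised as ``> 0``.  A pair of samples with an empty union raises.
    """
    data = presence.data if isinstance(presence, PresenceMatrix) else presence
    arr = data.to_numpy()
    arr = arr.astype(bool) if arr.dtype != bool else arr
    _check_matrix(arr)
    empty = [str(s) for s, t in zip(data.columns, arr.sum(axis=0)) if t == 0]
    if len(empty) >= 2:
        raise ValueError(
            "binary Jaccard undefined between empty presence sets: " + ", ".join(empty)
        )
    d = squareform(pdist(arr.T, metric="jaccard"))
    return DistanceMatrix(d, ids=[str(c) for c in data.columns])
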