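"""Coverage profiles: contig filtering, presence calls, core partition, abundances.

The input is a long-format coverage table summarising a read mapping of each
sample's reads against a co-assembled viral contig catalog: one record per
(sample, contig) with contig length, reads mapped, bases covered by at least
one read, and mean fold-coverage.  From it this module derives

* a filtered catalog (short or shallow contigs removed globally),
* binary presence calls from breadth of coverage (fraction of the contig
  covered; a contig counts as present at >= 75% breadth by default),
* the Venn-style partition of contigs into sample-subset regions, whose
  full-intersection region is the core virome, and
* length-adjusted relative abundances (reads per base, normalised per
  sample).

Missing (sample, contig) records mean zero coverage, not missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import FrozenSet, Mapping

import numpy as np
import pandas as pd

from phylosym.io import COVERAGE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "COVERAGE_COLUMNS",
    "PresenceMatrix",
    "SharedPartition",
    "validate_coverage_table",
    "filter_contigs",
    "call_presence",
    "partition_shared",
    "relative_abundance",
    "aggregate_by_taxon",
    "count_matrix",
]


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary contig-by-sample presence calls plus the threshold that made them.

    ``data`` is a boolean DataFrame (rows contigs, columns samples);
    ``breadth_threshold`` is recorded for provenance.
    """

    data: pd.DataFrame
    breadth_threshold: float

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def contigs(self) -> list:
        return list(self.data.index)

    def present_set(self, sample: str) -> FrozenSet[str]:
        col = self.data[sample]
        return frozenset(col.index[col])


@dataclass(frozen=True)
class SharedPartition:
    """Venn partition of the observed contigs over sample subsets.

    ``regions`` maps each nonempty sample subset to the contigs present in
    exactly that subset; only nonempty regions are stored.  ``core`` is the
    region of the full sample set (contigs present everywhere).
    """

    samples: tuple
    regions: Mapping[FrozenSet[str], FrozenSet[str]]
    core: FrozenSet[str] = field(default=frozenset())

    def region_sizes(self) -> dict:
        return {subset: len(c) for subset, c in self.regions.items()}

    def observed_contigs(self) -> FrozenSet[str]:
        out: set = set()
        for c in self.regions.values():
            out |= c
        return frozenset(out)


def validate_coverage_table(table: pd.DataFrame) -> None:
    """Raise ``ValueError`` on any violation of the coverage-table contract."""
    missing = [c for c in COVERAGE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"coverage table missing columns: {missing}")
    if table.duplicated(subset=["sample", "contig"]).any():
        dup = table[table.duplicated(subset=["sample", "contig"], keep=False)]
        raise ValueError(
            "duplicate (sample, contig) records: "
            + ", ".join(f"({r.sample}, {r.contig})" for r in dup.itertuples())
        )
    if (table["length"] <= 0).any():
        raise ValueError("contig lengths must be positive")
    if (table["reads"] < 0).any() or (table["mean_depth"] < 0).any():
        raise ValueError("reads and mean_depth must be non-negative")
    if ((table["bases_covered"] < 0) | (table["bases_covered"] > table["length"])).any():
        raise ValueError("bases_covered must lie in [0, length]")


def filter_contigs(
    table: pd.DataFrame, min_length: int = 500, min_depth: float = 5.0
) -> pd.DataFrame:
    """Drop short or shallow contigs from the catalog, globally across samples.

    A contig is removed everywhere if its length is below ``min_length`` or if
    its *maximum* per-sample mean depth is below ``min_depth`` (the catalog is
    co-assembled, so filtering is a property of the contig, not of one
    sample's mapping).  Boundary values are kept: exactly 500 bp and exactly
    5.0x survive the defaults.
    """
    if min_length < 0 or min_depth < 0:
        raise ValueError("filter thresholds must be non-negative")
    validate_coverage_table(table)
    per_contig = table.groupby("contig").agg(
        length=("length", "first"), max_depth=("mean_depth", "max")
    )
    keep = per_contig.index[
        (per_contig["length"] >= min_length) & (per_contig["max_depth"] >= min_depth)
    ]
    n_short = int((per_contig["length"] < min_length).sum())
    n_shallow = int(
        ((per_contig["length"] >= min_length) & (per_contig["max_depth"] < min_depth)).sum()
    )
    out = table[table["contig"].isin(keep)].reset_index(drop=True)
    logger.info(
        "filter_contigs: %d contigs in, %d removed (<%d bp: %d; max depth <%gx: %d), %d kept",
        len(per_contig), len(per_contig) - len(keep), min_length, n_short, min_depth,
        n_shallow, len(keep),
    )
    if out.empty:
        logger.warning("filter_contigs: no contigs survive the filters")
    return out


def call_presence(table: pd.DataFrame, breadth_threshold: float = 0.75) -> PresenceMatrix:
    """Call a contig present in a sample when breadth >= ``breadth_threshold``.

    Breadth is ``bases_covered / length``; the default 0.75 threshold is
    inclusive.  Contigs with no record for a sample are absent there.
    """
    if not 0 < breadth_threshold <= 1:
        raise ValueError("breadth_threshold must lie in (0, 1]")
    validate_coverage_table(table)
    work = table.assign(breadth=table["bases_covered"] / table["length"])
    wide = (
        work.pivot(index="contig", columns="sample", values="breadth")
        .fillna(0.0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    return PresenceMatrix(data=wide >= breadth_threshold, breadth_threshold=breadth_threshold)


def partition_shared(presence: PresenceMatrix) -> SharedPartition:
    """Partition observed contigs into Venn regions over the sample set."""
    samples = tuple(presence.samples)
    if len(samples) < 2:
        raise ValueError("partition_shared needs at least 2 samples")
    membership: dict = {}
    data = presence.data
    for contig in data.index:
        row = data.loc[contig]
        subset = frozenset(row.index[row])
        if subset:
            membership.setdefault(subset, set()).add(contig)
    regions = {s: frozenset(c) for s, c in membership.items()}
    core = regions.get(frozenset(samples), frozenset())
    return SharedPartition(samples=samples, regions=regions, core=core)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Length-adjusted relative abundances (reads per base, normalised).

    Per (sample, contig) the read density is ``reads / length``; each
    sample's densities are normalised to sum to 1.  An all-zero sample is
    left all-zero with a warning.  Result has ``attrs['mode'] = 'relative'``.
    """
    validate_coverage_table(table)
    if table.empty:
        raise ValueError("relative_abundance requires a nonempty coverage table")
    work = table.assign(density=table["reads"] / table["length"])
    wide = (
        work.pivot(index="contig", columns="sample", values="density")
        .fillna(0.0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    totals = wide.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning(
            "relative_abundance: all-zero sample(s) left as zeros: %s",
            ", ".join(map(str, totals.index[zero])),
        )
    safe = totals.replace(0, np.nan)
    rel = wide.div(safe, axis=1).fillna(0.0)
    rel.attrs["mode"] = "relative"
    return rel


def aggregate_by_taxon(rel: pd.DataFrame, taxon_map: pd.DataFrame) -> pd.DataFrame:
    """Sum relative abundances of contigs sharing a taxon label.

    ``taxon_map`` has columns ``contig`` and ``taxon``; contigs missing from
    the map fall into an ``unclassified`` bucket.  Column sums are preserved.
    """
    if rel.attrs.get("mode") != "relative":
        raise ValueError("aggregate_by_taxon expects a relative-mode abundance matrix")
    if taxon_map["contig"].duplicated().any():
        dups = taxon_map["contig"][taxon_map["contig"].duplicated()].tolist()
        raise ValueError(f"duplicate contigs in taxon map: {dups}")
    lookup = dict(zip(taxon_map["contig"], taxon_map["taxon"]))
    labels = [lookup.get(c, "unclassified") for c in rel.index]
    out = rel.groupby(pd.Index(labels, name="taxon")).sum().sort_index()
    out.attrs["mode"] = "relative"
    return out


def count_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Raw mapped-read counts as a contig-by-sample matrix (``mode='counts'``)."""
    validate_coverage_table(table)
    wide = (
        table.pivot(index="contig", columns="sample", values="reads")
        .fillna(0)
        .astype(np.int64)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    wide.attrs["mode"] = "counts"
    return wide


def _all_subsets(samples):  # pragma: no cover - small helper kept for reports
    for k in range(1, len(samples) + 1):
        yield from (frozenset(c) for c in combinations(samples, k))
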