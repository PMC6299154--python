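"""End-to-end orchestration: coverage table + host tree in, report bundle out.

Stage order: filter contigs -> presence calls -> core/shared partition ->
relative abundance (-> taxon aggregation) -> rarefaction replicates ->
beta-diversity distances -> UPGMA consensus dendrogram -> Monte Carlo
congruence test against the host phylogeny.  Every artifact is written as
plain text (TSV / newick / JSON) and the report carries full provenance
(config echo, derived seeds, library versions).  Identical config and
inputs give byte-identical artifacts; the report's timestamp is the single
non-deterministic field.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import scipy
import skbio
import yaml

from phylosym import io as psio
from phylosym._seeds import substream_seed
from phylosym.congruence import congruence_test
from phylosym.coverage import (
    aggregate_by_taxon,
    call_presence,
    count_matrix,
    filter_contigs,
    partition_shared,
    relative_abundance,
    validate_coverage_table,
)
from phylosym.dendrogram import consensus_dendrogram
from phylosym.diversity import binary_jaccard, bray_curtis, rarefaction_set

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults are the pipeline's standard constants.

    ``min_length`` 500 bp and ``min_depth`` 5x gate the contig catalog;
    presence needs ``breadth_threshold`` 0.75; counts are rarefied
    ``n_rarefactions`` = 10 times to ``rarefaction_depth`` = 16,400; the
    congruence null uses ``n_null`` = 100,000 random topologies.
    """

    coverage: str = ""
    host_tree: str = ""
    out_dir: str = "phylosym_out"
    taxon_map: Optional[str] = None
    min_length: int = 500
    min_depth: float = 5.0
    breadth_threshold: float = 0.75
    rarefaction_depth: int = 16_400
    n_rarefactions: int = 10
    beta_metric: str = "braycurtis"
    n_null: int = 100_000
    null_scheme: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        if self.beta_metric not in ("braycurtis", "jaccard"):
            raise ValueError("beta_metric must be 'braycurtis' or 'jaccard'")
        if self.null_scheme not in ("uniform", "yule"):
            raise ValueError("null_scheme must be 'uniform' or 'yule'")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load a flat key-value (YAML) config file; kwargs override file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a flat key-value mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class ReportBundle:
    """All pipeline outputs plus provenance, mirrored to ``report.json``."""

    config: PipelineConfig
    partition_sizes: dict
    core_size: int
    n_contigs_input: int
    n_contigs_filtered: int
    consensus_newick: str
    congruence: dict
    taxon_table: Optional[pd.DataFrame] = None
    artifacts: List[str] = field(default_factory=list)
    derived_seeds: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with stage name for the CLI
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis; write artifacts under ``config.out_dir``.

    On any stage failure, partially written artifacts are removed and a
    ``RuntimeError`` naming the stage is raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        written.append(path)
        return path

    try:
        return _run(config, out_dir, emit, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run(config: PipelineConfig, out_dir: Path, emit, written) -> ReportBundle:
    table = _load_inputs_stage(config)
    host = _load_tree_stage(config, table)

    filtered = _filter_stage(config, table)
    emit("coverage_filtered.tsv", lambda p: psio.write_coverage_table(filtered, p))

    presence = _presence_stage(config, filtered)
    emit("presence.tsv", lambda p: psio.write_matrix_tsv(presence.data.astype(int), p))
    partition = partition_shared(presence)
    partition_sizes = {
        "&".join(sorted(k)): v for k, v in sorted(partition.region_sizes().items(),
                                                  key=lambda kv: sorted(kv[0]))
    }
    logger.info("partition: %d regions, core size %d", len(partition_sizes), len(partition.core))

    rel = _abundance_stage(filtered)
    emit("relative_abundance.tsv", lambda p: psio.write_matrix_tsv(rel, p))
    taxon_table = None
    if config.taxon_map:
        taxon_table = _taxon_stage(config, rel)
        emit("taxon_abundance.tsv", lambda p: psio.write_matrix_tsv(taxon_table, p))

    rarefaction_seed = substream_seed(config.seed, "rarefaction")
    null_seed = substream_seed(config.seed, "null_topologies")

    dists = _distance_stage(config, filtered, presence, rarefaction_seed)
    for r, dm in enumerate(dists):
        emit(f"distance_{config.beta_metric}_rep{r:02d}.tsv",
             lambda p, dm=dm: psio.write_distance_matrix(dm, p))

    consensus = _consensus_stage(dists)
    emit("consensus_dendrogram.nwk", lambda p: psio.write_tree(consensus, p))

    result = _congruence_stage(config, host, consensus, null_seed)
    emit("congruence.json",
         lambda p: p.write_text(json.dumps(result.to_dict(), indent=2) + "\n"))

    bundle = ReportBundle(
        config=config,
        partition_sizes=partition_sizes,
        core_size=len(partition.core),
        n_contigs_input=table["contig"].nunique(),
        n_contigs_filtered=filtered["contig"].nunique(),
        consensus_newick=psio.tree_to_newick(consensus).strip(),
        congruence=result.to_dict(),
        taxon_table=taxon_table,
        derived_seeds={"rarefaction": rarefaction_seed, "null_topologies": null_seed},
    )
    report = {
        "config": asdict(config),
        "versions": {
            "phylosym": _version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-bio": skbio.__version__,
        },
        "derived_seeds": bundle.derived_seeds,
        "n_contigs_input": bundle.n_contigs_input,
        "n_contigs_filtered": bundle.n_contigs_filtered,
        "partition_sizes": bundle.partition_sizes,
        "core_size": bundle.core_size,
        "consensus_dendrogram": bundle.consensus_newick,
        "congruence": bundle.congruence,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    emit("report.json", lambda p: p.write_text(json.dumps(report, indent=2) + "\n"))
    bundle.artifacts = [str(p) for p in written]
    return bundle


def _version() -> str:
    import phylosym

    return phylosym.__version__


@_stage("load-coverage")
def _load_inputs_stage(config: PipelineConfig) -> pd.DataFrame:
    table = psio.read_coverage_table(config.coverage)
    validate_coverage_table(table)
    logger.info("loaded coverage: %d records, %d samples, %d contigs",
                len(table), table["sample"].nunique(), table["contig"].nunique())
    return table


@_stage("load-host-tree")
def _load_tree_stage(config: PipelineConfig, table: pd.DataFrame):
    host = psio.read_tree(config.host_tree)
    leaves = {t.name for t in host.tips()}
    samples = set(table["sample"].unique())
    missing = samples - leaves
    if missing:
        raise ValueError(f"host tree is missing sample label(s): {sorted(missing)}")
    if leaves - samples:
        host = host.shear(sorted(samples))
    return host


@_stage("filter-contigs")
def _filter_stage(config, table):
    return filter_contigs(table, min_length=config.min_length, min_depth=config.min_depth)


@_stage("call-presence")
def _presence_stage(config, filtered):
    return call_presence(filtered, breadth_threshold=config.breadth_threshold)


@_stage("relative-abundance")
def _abundance_stage(filtered):
    return relative_abundance(filtered)


@_stage("taxon-aggregation")
def _taxon_stage(config, rel):
    return aggregate_by_taxon(rel, psio.read_taxon_map(config.taxon_map))


@_stage("beta-diversity")
def _distance_stage(config, filtered, presence, rarefaction_seed):
    if config.beta_metric == "jaccard":
        # presence/absence from the breadth rule: a single replicate
        return [binary_jaccard(presence)]
    counts = count_matrix(filtered)
    reps = rarefaction_set(
        counts, config.rarefaction_depth, config.n_rarefactions, rarefaction_seed
    )
    return [bray_curtis(rep) for rep in reps]


@_stage("consensus-dendrogram")
def _consensus_stage(dists):
    return consensus_dendrogram(dists)


@_stage("congruence-test")
def _congruence_stage(config, host, consensus, null_seed):
    return congruence_test(
        host,
        consensus,
        n_null=config.n_null,
        metric="both",
        scheme=config.null_scheme,
        seed=null_seed,
    )


def validate_inputs(
    coverage: str, host_tree: str, taxon_map: Optional[str] = None
) -> List[dict]:
    """Schema and consistency diagnostics for pipeline inputs.

    Returns a (possibly empty) list of ``{"code", "message"}`` problems
    without running the pipeline; never raises for data problems.
    """
    problems: List[dict] = []

    def add(code, message):
        problems.append({"code": code, "message": message})

    table = None
    try:
        table = psio.read_coverage_table(coverage)
    except Exception as exc:
        add("coverage-unreadable", str(exc))
    if table is not None:
        if table.duplicated(subset=["sample", "contig"]).any():
            add("coverage-duplicate-records", "duplicated (sample, contig) rows")
        if (table["length"] <= 0).any():
            add("coverage-bad-length", "non-positive contig length")
        for col in ("reads", "bases_covered"):
            vals = table[col]
            if (vals < 0).any():
                add(f"coverage-negative-{col}", f"negative values in '{col}'")
            if not np.allclose(vals, np.round(vals)):
                add(f"coverage-noninteger-{col}", f"non-integer values in '{col}'")
        if (table["mean_depth"] < 0).any():
            add("coverage-negative-depth", "negative mean_depth")
        if ((table["bases_covered"] > table["length"])).any():
            add("coverage-breadth-overflow", "bases_covered exceeds contig length")

    tree = None
    try:
        tree = psio.read_tree(host_tree)
    except Exception as exc:
        add("tree-unreadable", str(exc))
    if tree is not None:
        names = [t.name for t in tree.tips()]
        if any(n is None for n in names):
            add("tree-unlabeled-leaf", "host tree has unlabeled leaves")
        if len(set(names)) != len(names):
            add("tree-duplicate-leaves", "duplicate leaf labels in host tree")
        if table is not None:
            missing = set(table["sample"].unique()) - set(names)
            if missing:
                add("label-mismatch",
                    f"samples absent from host tree: {sorted(missing)}")

    if taxon_map is not None:
        try:
            tm = psio.read_taxon_map(taxon_map)
            if tm["contig"].duplicated().any():
                add("taxon-map-duplicates", "duplicate contigs in taxon map")
        except Exception as exc:
            add("taxon-map-unreadable", str(exc))

    return problems
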