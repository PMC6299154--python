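"""Readers and writers for the package's plain-text interchange formats.

Formats
-------
coverage table TSV
    Long format, one record per (sample, contig), header
    ``sample\tcontig\tlength\treads\tbases_covered\tmean_depth``.
matrix TSV
    Wide format, rows = contigs, columns = samples, first column ``contig``.
distance matrix TSV
    Square, header row and first column of sample IDs, 12 significant digits.
taxon map TSV
    Two columns ``contig\ttaxon``.
trees
    Newick via scikit-bio; leaf labels round-trip exactly (underscores are
    not rewritten to spaces).
"""

from __future__ import annotations

import io as _io
from os import PathLike
from typing import Union

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

PathType = Union[str, PathLike]

COVERAGE_COLUMNS = ["sample", "contig", "length", "reads", "bases_covered", "mean_depth"]


def read_coverage_table(path: PathType) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "contig": str})
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coverage table {path} missing columns: {missing}")
    return df[COVERAGE_COLUMNS]


def write_coverage_table(table: pd.DataFrame, path: PathType) -> None:
    table[COVERAGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: PathType) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="contig")
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: PathType) -> None:
    out = matrix.copy()
    out.index.name = "contig"
    out.to_csv(path, sep="\t")


def read_taxon_map(path: PathType) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"contig", "taxon"}.issubset(df.columns):
        raise ValueError(f"taxon map {path} must have columns 'contig' and 'taxon'")
    return df[["contig", "taxon"]]


def write_taxon_map(taxon_map: pd.DataFrame, path: PathType) -> None:
    taxon_map[["contig", "taxon"]].to_csv(path, sep="\t", index=False)


def read_distance_matrix(path: PathType) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    data = df.to_numpy(dtype=float)
    # tolerate last-digit asymmetry from the 12-significant-digit format
    data = (data + data.T) / 2.0
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(data, ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path: PathType) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_tree(path: PathType) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)


def parse_newick(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick), format="newick", convert_underscores=False)


def write_tree(tree: TreeNode, path: PathType) -> None:
    tree.write(str(path), format="newick")


def tree_to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()
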