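"""Readers and writers for the tabular and text formats used by the pipeline.

All on-disk formats are plain text: TSV for matrices and metadata, GMT for
gene-set collections, CDT for clustered heat-map tables, Newick for
dendrograms, and 4-line Phred+33 FASTQ for reads.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree

FLOAT_FMT = "%.6g"

CATALOG_COLUMNS = ["strain_id", "gene", "uptag"]
DESIGN_COLUMNS = ["sample_id", "compound", "role", "pair_id", "batch", "replicate"]


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog missing columns: {missing}")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "compound": str,
                                            "role": str, "pair_id": str,
                                            "batch": str})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design missing columns: {missing}")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path, index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# GMT gene-set collections


def write_gmt(sets: "OrderedDict[str, list[str]]", path,
              descriptions: dict | None = None) -> None:
    """Write gene sets in GMT: name <tab> description <tab> members..."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> "OrderedDict[str, list[str]]":
    sets: OrderedDict[str, list[str]] = OrderedDict()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            sets[parts[0]] = parts[2:]
    return sets


# ---------------------------------------------------------------------------
# Newick export of a scipy linkage


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths.

    Branch length of a node is the difference between its parent's merge
    height and its own (leaves have height 0).
    """
    tree = to_tree(linkage)

    def _fmt(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _fmt(node.left, node.dist)
        right = _fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    if tree.is_leaf():
        return f"{labels[tree.id]}:0;"
    left = _fmt(tree.left, tree.dist)
    right = _fmt(tree.right, tree.dist)
    return f"({left},{right});"


# ---------------------------------------------------------------------------
# CDT (clustered data table) for TreeView-style viewers


def write_cdt(matrix: pd.DataFrame, path, gene_names: dict | None = None) -> None:
    """Write a reordered matrix as a CDT file.

    Layout: header ``GID UID NAME GWEIGHT <samples>``, one ``EWEIGHT`` row,
    then one row per gene in the order of ``matrix.index``. ``gene_names``
    optionally maps gene id -> display name (defaults to the id).
    """
    gene_names = gene_names or {}
    cols = [str(c) for c in matrix.columns]
    with open(path, "w") as fh:
        fh.write("\t".join(["GID", "UID", "NAME", "GWEIGHT", *cols]) + "\n")
        fh.write("\t".join(["EWEIGHT", "", "", "", *["1"] * len(cols)]) + "\n")
        for i, (gene, row) in enumerate(matrix.iterrows()):
            vals = ["" if pd.isna(v) else FLOAT_FMT % v for v in row.to_numpy()]
            name = gene_names.get(gene, gene)
            fh.write("\t".join([f"GENE{i}X", str(gene), str(name), "1", *vals]) + "\n")


def read_cdt(path) -> pd.DataFrame:
    """Read a CDT written by :func:`write_cdt` back into a DataFrame."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = header[4:]
        rows, index = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "EWEIGHT":
                continue
            index.append(parts[1])
            rows.append([np.nan if v == "" else float(v) for v in parts[4:]])
    return pd.DataFrame(rows, index=pd.Index(index, name="gene"), columns=cols)
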