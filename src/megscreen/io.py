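"""Validated TSV readers and writers for all pipeline tables.

All tables are tab-separated with a header row; writers may prepend ``#``
comment lines (provenance: config hash, seed) which readers skip. Floats are
written at repr precision so write-then-read round-trips are lossless.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError

GENE_COLUMN = "gene_id"
METADATA_COLUMNS = ["sample_id", "patient_id", "group", "timepoint"]


def _write_with_comments(frame: pd.DataFrame, path, comments=(), index=False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def write_expression(expr: pd.DataFrame, path, comments=()) -> None:
    out = expr.reset_index()
    out = out.rename(columns={out.columns[0]: GENE_COLUMN})
    _write_with_comments(out, path, comments)


def read_expression(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if raw.columns[0] != GENE_COLUMN:
        raise InputError(f"{path}: first column must be {GENE_COLUMN!r}, got {raw.columns[0]!r}")
    dup_genes = raw[GENE_COLUMN][raw[GENE_COLUMN].duplicated()]
    if not dup_genes.empty:
        raise InputError(f"{path}: duplicate gene identifiers: {sorted(set(dup_genes))[:5]}")
    samples = list(raw.columns[1:])
    if len(set(samples)) != len(samples):
        raise InputError(f"{path}: duplicate sample identifiers")
    expr = raw.set_index(GENE_COLUMN)
    for col in expr.columns:
        numeric = pd.to_numeric(expr[col], errors="coerce")
        bad = numeric.isna() & expr[col].notna()
        if bad.any():
            gene = expr.index[bad][0]
            raise InputError(f"{path}: non-numeric expression value at gene {gene!r}, sample {col!r}")
        expr[col] = numeric
    if expr.isna().any().any():
        gene = expr.index[expr.isna().any(axis=1)][0]
        raise InputError(f"{path}: missing expression value at gene {gene!r}")
    neg = expr < 0
    if neg.any().any():
        gene = expr.index[neg.any(axis=1)][0]
        col = expr.columns[neg.loc[gene].to_numpy().nonzero()[0][0]]
        raise InputError(
            f"{path}: negative expression at gene {gene!r}, sample {col!r} "
            "(network weighting requires nonnegative intensities)"
        )
    return expr.astype(float)


def write_metadata(meta: pd.DataFrame, path, comments=()) -> None:
    out = meta.reset_index()
    _write_with_comments(out[METADATA_COLUMNS], path, comments)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "patient_id": str, "group": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise InputError(f"{path}: missing metadata columns {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta["sample_id"][meta["sample_id"].duplicated()]
        raise InputError(f"{path}: duplicate sample identifiers: {sorted(set(dups))[:5]}")
    meta["timepoint"] = pd.to_numeric(meta["timepoint"], errors="coerce").astype("Int64")
    return meta.set_index("sample_id")


def write_network(network: nx.Graph, path, comments=()) -> None:
    edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in network.edges()), columns=["gene_a", "gene_b"])
    _write_with_comments(edges, path, comments)


def read_network(path, nodes=None) -> nx.Graph:
    edges = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("gene_a", "gene_b"):
        if col not in edges.columns:
            raise InputError(f"{path}: missing edge-list column {col!r}")
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    for a, b in edges[["gene_a", "gene_b"]].itertuples(index=False):
        if a == b:
            raise InputError(f"{path}: self-loop on gene {a!r}")
        graph.add_edge(a, b)  # (a,b)/(b,a) duplicates collapse to one edge
    return graph


def write_table(frame: pd.DataFrame, path, comments=(), index=False) -> None:
    _write_with_comments(frame, path, comments, index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def check_matched(expr: pd.DataFrame, meta: pd.DataFrame, path_hint: str = "") -> None:
    """Metadata rows must match expression columns one-to-one."""
    expr_samples = list(expr.columns)
    meta_samples = list(meta.index)
    if sorted(expr_samples) != sorted(meta_samples):
        only_expr = sorted(set(expr_samples) - set(meta_samples))[:5]
        only_meta = sorted(set(meta_samples) - set(expr_samples))[:5]
        raise InputError(
            f"{path_hint} expression/metadata sample mismatch: "
            f"only in expression {only_expr}, only in metadata {only_meta}"
        )
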