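"""Readers and writers for the tabular and graph formats the pipeline touches.

Conventions: ASV tables and taxonomy maps are TSV (first column = id, header
= other axis); metadata is CSV; networks are written both as GraphML and as a
flat edge-list TSV; all result tables are tidy TSV, one row per entity.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    AsvTable,
    CooccurrenceNetwork,
    ValidationError,
    validate_sample_metadata,
    validate_taxonomy,
)

__all__ = [
    "read_asv_table",
    "write_asv_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "write_network",
    "read_network",
    "write_tidy",
]

PathLike = Union[str, Path]

ORIENTATIONS = ("samples_in_rows", "samples_in_columns")


def read_asv_table(path: PathLike, orientation: str = "samples_in_rows") -> AsvTable:
    """Read a TSV count table; ``orientation`` declares which axis is samples.

    The returned table is always samples x ASVs.  Non-numeric or negative
    cells raise a parse error naming the offending row/column.
    """
    if orientation not in ORIENTATIONS:
        raise ValidationError(
            f"orientation must be one of {ORIENTATIONS}, got {orientation!r}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise ValidationError(
                f"non-numeric count at row {row!r}, column {col!r} in {path}"
            )
        df[col] = coerced
    if orientation == "samples_in_columns":
        df = df.T
    return AsvTable(df)


def write_asv_table(table: AsvTable, path: PathLike) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_metadata(path: PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path)
    meta["sample_id"] = meta["sample_id"].astype(str)
    return validate_sample_metadata(meta)


def write_sample_metadata(meta: pd.DataFrame, path: PathLike) -> None:
    meta.to_csv(path, index=False)


def read_taxonomy(path: PathLike) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t")
    tax["asv_id"] = tax["asv_id"].astype(str)
    return validate_taxonomy(tax)


def write_taxonomy(tax: pd.DataFrame, path: PathLike) -> None:
    tax.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def write_network(
    net: CooccurrenceNetwork,
    graphml_path: PathLike,
    edgelist_path: PathLike | None = None,
) -> None:
    """Write a network as GraphML plus a flat edge-list TSV.

    The GraphML round-trips node/edge sets and float attributes exactly
    (floats are serialized via ``repr``); the TSV columns are
    node_u, node_v, rho, sign, q.
    """
    graphml_path = Path(graphml_path)
    if edgelist_path is None:
        edgelist_path = graphml_path.with_suffix(".edges.tsv")
    nx.write_graphml(net.graph, graphml_path)
    df = net.edges_dataframe()
    df.to_csv(edgelist_path, sep="\t", index=False, float_format="%.17g")


def read_network(graphml_path: PathLike) -> CooccurrenceNetwork:
    g = nx.read_graphml(graphml_path)
    out = nx.Graph()
    out.add_nodes_from(sorted(str(n) for n in g.nodes))
    for u, v, d in g.edges(data=True):
        rho = float(d["rho"])
        out.add_edge(
            str(u),
            str(v),
            rho=rho,
            q=float(d.get("q", np.nan)),
            sign=d.get("sign", "+" if rho >= 0 else "-"),
        )
    return CooccurrenceNetwork(out)


def write_tidy(df: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    """Write a result table as tidy TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
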