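"""Readers and writers for metanetwork inputs and outputs.

All tabular formats are comma-separated UTF-8 with a mandatory header and
``.`` decimal.  Graphs round-trip through edge-list CSV
(``resource,consumer[,weight]``) or GraphML; community matrices through an
abundance CSV whose first column is ``network``; trophic tables through a
CSV whose first column holds the finest node names and each further
column one coarser resolution (fine -> coarse order).
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import pandas as pd

from .core import AbundanceTable, MetanetworkError, Metaweb, TrophicTable

__all__ = [
    "read_metaweb",
    "write_metaweb",
    "read_abundances",
    "write_abundances",
    "read_trophic_table",
    "write_trophic_table",
    "read_interaction_matrix",
]


def read_metaweb(path: str | Path, reverse: bool = False) -> Metaweb:
    """Read a metaweb from edge-list CSV or GraphML (by extension).

    Edges are taken as resource -> consumer; ``reverse=True`` flips files
    encoded predator -> prey.  Duplicate edges collapse by summing weights
    (with a warning); malformed CSV rows are reported with line numbers.
    """
    path = Path(path)
    if path.suffix.lower() in {".graphml", ".xml"}:
        g = nx.read_graphml(path)
        if not g.is_directed():
            raise MetanetworkError(f"{path}: GraphML graph must be directed")
        edges = [(u, v, float(d.get("weight", 1.0))) for u, v, d in g.edges(data=True)]
    else:
        edges = _read_edge_csv(path)
    if reverse:
        edges = [(v, u, w) for u, v, w in edges]
    return Metaweb(edges)


def _read_edge_csv(path: Path) -> list[tuple[str, str, float]]:
    edges = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise MetanetworkError(f"{path}: expected header 'resource,consumer[,weight]'")
        for ln, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise MetanetworkError(f"{path}:{ln}: expected at least 2 columns, got {row}")
            w = 1.0
            if len(row) >= 3 and row[2].strip():
                try:
                    w = float(row[2])
                except ValueError:
                    raise MetanetworkError(f"{path}:{ln}: weight {row[2]!r} is not a number")
            edges.append((row[0].strip(), row[1].strip(), w))
    return edges


def write_metaweb(metaweb: Metaweb, path: str | Path) -> None:
    """Write a metaweb as edge-list CSV or GraphML (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".graphml", ".xml"}:
        nx.write_graphml(metaweb.graph, path)
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["resource", "consumer", "weight"])
        for u, v, wt in metaweb.edges:
            w.writerow([u, v, wt])


def read_interaction_matrix(path: str | Path, reverse: bool = False) -> Metaweb:
    """Read a food-web interaction matrix CSV (Web-of-Life export style).

    Rows are resources, columns consumers, positive entries are edge
    weights; the first column holds row names.  ``reverse=True`` for
    matrices encoded predator-in-rows.
    """
    m = pd.read_csv(path, index_col=0)
    edges = []
    for r in m.index:
        for c in m.columns:
            w = float(m.loc[r, c])
            if w > 0:
                edges.append((str(r), str(c), w))
    if reverse:
        edges = [(v, u, w) for u, v, w in edges]
    return Metaweb(edges)


def read_abundances(path: str | Path) -> AbundanceTable:
    """Read the community matrix: first column ``network``, then node names."""
    df = pd.read_csv(path)
    if df.columns[0] != "network":
        raise MetanetworkError(
            f"{path}: first column must be 'network', got {df.columns[0]!r}"
        )
    return AbundanceTable(df.set_index("network"))


def write_abundances(table: AbundanceTable, path: str | Path) -> None:
    out = table.values.copy()
    out.index.name = "network"
    out.to_csv(path)


def read_trophic_table(path: str | Path) -> TrophicTable:
    """Read a trophic table: finest node names first, then coarser columns."""
    df = pd.read_csv(path, dtype=str)
    return TrophicTable(df.set_index(df.columns[0]))


def write_trophic_table(table: TrophicTable, path: str | Path) -> None:
    table.mapping.to_csv(path)
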