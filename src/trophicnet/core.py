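"""Core data model for trophic metanetworks.

A *metaweb* is the regional pool of species (nodes) and their potential
trophic interactions (directed edges, resource -> consumer).  Together with
a community matrix ``P`` of local relative abundances it induces one *local
network* per community: the vertex-induced subgraph of the metaweb
restricted to locally present species.  An optional *trophic table* maps
every node to nested group labels at one or more coarser resolutions,
enabling aggregation of both abundances and interaction probabilities.

The central container is :class:`Metanetwork`, built with
:func:`build_metanet` and extended with :func:`append_agg_nets`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("trophicnet")

__all__ = [
    "Metaweb",
    "AbundanceTable",
    "TrophicTable",
    "LocalNetwork",
    "Metanetwork",
    "MetanetworkError",
    "build_metanet",
    "aggregate_network",
    "append_agg_nets",
    "trophic_table_tree",
]

#: node-attribute key for relative abundance
AB = "ab"
#: node-attribute key for trophic level
TL = "TL"
#: name under which the metaweb appears in tables and reports
METAWEB = "metaweb"


class MetanetworkError(ValueError):
    """Raised when inputs violate the metanetwork contracts."""


# ---------------------------------------------------------------------------
# Metaweb
# ---------------------------------------------------------------------------


class Metaweb:
    """Directed, weakly connected interaction network over named nodes.

    Edges point resource -> consumer (direction of energy flow), so basal
    resources have in-degree 0.  Edge weights ``pi`` are non-negative link
    probabilities or diet fractions; unweighted input gets weight 1.

    Parameters
    ----------
    edges:
        Iterable of ``(resource, consumer)`` or ``(resource, consumer, weight)``.
    nodes:
        Optional extra node names (isolated nodes are rejected anyway by the
        connectivity requirement, but names appearing only here are kept for
        the error message).
    """

    def __init__(self, edges: Iterable[tuple], nodes: Iterable[str] | None = None):
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        dups = []
        for e in edges:
            if len(e) == 2:
                u, v, w = e[0], e[1], 1.0
            else:
                u, v, w = e[0], e[1], float(e[2])
            if u == v:
                raise MetanetworkError(f"self-loop on node {u!r} is not allowed in a metaweb")
            if w < 0:
                raise MetanetworkError(f"negative weight {w} on edge {u!r}->{v!r}")
            if g.has_edge(u, v):
                dups.append((u, v))
                g[u][v]["weight"] += w
            else:
                g.add_edge(u, v, weight=w)
        if dups:
            warnings.warn(
                f"{len(dups)} duplicate edge(s) collapsed by summing weights, e.g. {dups[0]}",
                stacklevel=2,
            )
        if g.number_of_nodes() == 0:
            raise MetanetworkError("empty metaweb")
        if not nx.is_weakly_connected(g):
            comps = [sorted(c) for c in nx.weakly_connected_components(g)]
            raise MetanetworkError(
                "metaweb must be weakly connected; found "
                f"{len(comps)} components: {comps}"
            )
        self.graph: nx.DiGraph = g

    # -- container protocol -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def __contains__(self, node) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Metaweb({len(self)} nodes, {self.graph.number_of_edges()} edges)"

    def is_weighted(self) -> bool:
        """True when any edge weight differs from 1."""
        return any(d["weight"] != 1.0 for _, _, d in self.graph.edges(data=True))

    def basal_nodes(self) -> list[str]:
        """Nodes with no resources (in-degree 0)."""
        return [n for n, d in self.graph.in_degree() if d == 0]


# ---------------------------------------------------------------------------
# AbundanceTable
# ---------------------------------------------------------------------------


class AbundanceTable:
    """Community matrix **P**: one row per local network, one column per node.

    Rows are rescaled to sum to one on ingestion (relative abundances);
    the raw row totals are kept in :attr:`raw_totals`.
    """

    def __init__(self, values: pd.DataFrame):
        df = values.astype(float).copy()
        if df.index.has_duplicates:
            raise MetanetworkError("duplicate local-network names in abundance table")
        if df.columns.has_duplicates:
            raise MetanetworkError("duplicate node names in abundance table")
        if (df.values < 0).any():
            bad = df.columns[(df.values < 0).any(axis=0)][0]
            raise MetanetworkError(f"negative abundance in column {bad!r}")
        totals = df.sum(axis=1)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise MetanetworkError(f"local network {bad!r} has no positive abundance")
        self.raw_totals: pd.Series = totals
        self.values: pd.DataFrame = df.div(totals, axis=0)

    @property
    def network_names(self) -> list[str]:
        return list(self.values.index)

    def row(self, name: str) -> pd.Series:
        return self.values.loc[name]

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# TrophicTable
# ---------------------------------------------------------------------------


class TrophicTable:
    """Nested node-to-group mapping at one or more resolutions.

    The first (finest) resolution is the node names themselves; every
    further column assigns each node to a coarser group.  Partitions must be
    nested: a group at one resolution maps to exactly one group at the next.
    """

    def __init__(self, mapping: pd.DataFrame):
        df = mapping.astype(str).copy()
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise MetanetworkError(f"node {dup!r} appears twice in the trophic table")
        self.mapping: pd.DataFrame = df
        self._validate_nested()

    @property
    def finest_name(self) -> str:
        return self.mapping.index.name or "nodes"

    @property
    def resolutions(self) -> list[str]:
        """Resolution names, finest first."""
        return [self.finest_name] + list(self.mapping.columns)

    @property
    def coarser_resolutions(self) -> list[str]:
        return list(self.mapping.columns)

    def _validate_nested(self):
        cols = [self.mapping.index.to_series().astype(str)] + [
            self.mapping[c] for c in self.mapping.columns
        ]
        for fine, coarse in zip(cols[:-1], cols[1:]):
            n_images = pd.DataFrame({"f": fine.values, "c": coarse.values}).groupby("f")["c"].nunique()
            if (n_images > 1).any():
                g = n_images.index[n_images > 1][0]
                tgt = sorted(set(coarse.values[fine.values == g]))
                raise MetanetworkError(
                    f"partitions not nested: group {g!r} maps to several "
                    f"coarser groups {tgt}"
                )

    def partition(self, resolution: str) -> pd.Series:
        """Finest-node -> group label at ``resolution``."""
        if resolution == self.finest_name:
            return pd.Series(self.mapping.index, index=self.mapping.index)
        if resolution not in self.mapping.columns:
            raise MetanetworkError(
                f"unknown resolution {resolution!r}; available: {self.resolutions}"
            )
        return self.mapping[resolution]

    def groups(self, resolution: str) -> list[str]:
        return sorted(self.partition(resolution).unique())


def trophic_table_tree(table: TrophicTable) -> nx.DiGraph:
    """Containment forest of groups across resolutions.

    Nodes are ``(resolution, label)`` pairs; an edge points from each group
    to the coarser group containing it.  With a single coarsest group the
    forest is a tree.  Nestedness violations raise at table construction,
    so this function also serves as its structural witness.
    """
    tree = nx.DiGraph()
    res = table.resolutions
    for r in res:
        for g in table.groups(r):
            tree.add_node((r, g), resolution=r, label=g)
    for fine, coarse in zip(res[:-1], res[1:]):
        pf, pc = table.partition(fine), table.partition(coarse)
        for node in table.mapping.index:
            tree.add_edge((fine, pf[node]), (coarse, pc[node]))
    return tree


# ---------------------------------------------------------------------------
# Local networks and the metanetwork container
# ---------------------------------------------------------------------------


@dataclass
class LocalNetwork:
    """Vertex-induced subgraph of the metaweb for one local community.

    ``graph`` keeps metaweb edge weights and stores relative abundance under
    the ``"ab"`` node attribute.  Unlike the metaweb a local network may be
    disconnected (sampling effects).
    """

    name: str
    graph: nx.DiGraph
    abundances: pd.Series

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LocalNetwork({self.name!r}: {self.graph.number_of_nodes()} nodes, "
            f"{self.graph.number_of_edges()} edges)"
        )


@dataclass
class Metanetwork:
    """A metaweb plus its abundance-induced local networks.

    ``aggregated`` maps each coarser resolution to a dict with keys
    ``"metaweb"`` and every local-network name, each holding the aggregated
    :class:`LocalNetwork`-shaped object at that resolution.  ``layouts``
    stores embedded coordinates keyed by ``(network, resolution, beta)``.
    """

    metaweb: Metaweb
    locals: dict[str, LocalNetwork] = field(default_factory=dict)
    trophic_table: TrophicTable | None = None
    aggregated: dict[str, dict[str, LocalNetwork]] = field(default_factory=dict)
    layouts: dict[tuple, pd.DataFrame] = field(default_factory=dict)

    @property
    def finest_resolution(self) -> str:
        return self.trophic_table.finest_name if self.trophic_table else "nodes"

    @property
    def resolutions(self) -> list[str]:
        return (
            self.trophic_table.resolutions if self.trophic_table else [self.finest_resolution]
        )

    def network_names(self) -> list[str]:
        return [METAWEB] + list(self.locals)

    def get_network(self, name: str, resolution: str | None = None) -> LocalNetwork:
        """Return the (possibly aggregated) network called ``name``.

        ``resolution=None`` or the finest resolution returns the original;
        coarser resolutions require :func:`append_agg_nets` to have run.
        """
        if resolution in (None, self.finest_resolution):
            if name == METAWEB:
                ab = _uniform_abundance(self.metaweb.graph)
                g = self.metaweb.graph.copy()
                nx.set_node_attributes(g, ab.to_dict(), AB)
                return LocalNetwork(METAWEB, g, ab)
            if name not in self.locals:
                raise MetanetworkError(
                    f"unknown network {name!r}; have {self.network_names()}"
                )
            return self.locals[name]
        if resolution not in self.aggregated:
            raise MetanetworkError(
                f"resolution {resolution!r} not appended; run append_agg_nets first"
            )
        nets = self.aggregated[resolution]
        if name not in nets:
            raise MetanetworkError(
                f"unknown network {name!r}; have {self.network_names()}"
            )
        return nets[name]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Metanetwork({len(self.metaweb)} metaweb nodes, "
            f"{len(self.locals)} local networks, "
            f"resolutions={self.resolutions})"
        )


def _uniform_abundance(g: nx.DiGraph) -> pd.Series:
    n = g.number_of_nodes()
    return pd.Series(1.0 / n, index=list(g.nodes))


# ---------------------------------------------------------------------------
# build_metanet
# ---------------------------------------------------------------------------


def build_metanet(
    metaweb: Metaweb,
    abundances: AbundanceTable | None = None,
    trophic_table: TrophicTable | None = None,
) -> Metanetwork:
    """Assemble a :class:`Metanetwork` from the triplet ``(G*, P, T)``.

    Each abundance row induces one local network: the vertex-induced
    subgraph of the metaweb on the nodes with positive abundance.  Without
    abundances the metanetwork holds the metaweb alone.

    Raises
    ------
    MetanetworkError
        If an abundance column or trophic-table row names a node absent
        from the metaweb (matching is exact and case-sensitive), or if the
        trophic table does not cover every metaweb node.
    """
    locs: dict[str, LocalNetwork] = {}
    if abundances is not None:
        unknown = [c for c in abundances.values.columns if c not in metaweb]
        if unknown:
            raise MetanetworkError(
                f"abundance table names unknown node(s) {unknown}; "
                "node matching is exact and case-sensitive"
            )
        for name in abundances.network_names:
            row = abundances.row(name)
            present = list(row.index[row > 0])
            sub = metaweb.graph.subgraph(present).copy()
            ab = row[present]
            nx.set_node_attributes(sub, ab.to_dict(), AB)
            locs[str(name)] = LocalNetwork(str(name), sub, ab)
    if trophic_table is not None:
        unknown = [n for n in trophic_table.mapping.index if n not in metaweb]
        if unknown:
            raise MetanetworkError(f"trophic table names unknown node(s) {unknown}")
        missing = [n for n in metaweb.nodes if n not in trophic_table.mapping.index]
        if missing:
            raise MetanetworkError(
                f"trophic table must cover every metaweb node; missing {missing}"
            )
    if metaweb.is_weighted():
        logger.info("metaweb carries edge weights; trophic levels use binary degrees by default")
    return Metanetwork(metaweb=metaweb, locals=locs, trophic_table=trophic_table)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_network(
    graph: nx.DiGraph,
    abundances: pd.Series | Mapping[str, float] | None,
    partition: Mapping[str, str],
) -> tuple[nx.DiGraph, pd.Series]:
    """Aggregate a network over a node partition.

    Group abundance is the plain sum, and the group-to-group interaction
    probability is the abundance-weighted mean of pairwise link weights::

        p~_q   = sum_{k in C_q} p_k
        pi~_ql = sum_{k in C_q, k' in C_l} pi_kk' p_k p_k'
                 / (sum_{k in C_q} p_k * sum_{k' in C_l} p_k')

    An aggregated edge ``q -> l`` exists iff ``pi~_ql > 0`` (self-loops may
    appear).  Without abundances, uniform weights ``p_k = 1/n`` are used.
    Groups whose present members carry zero total abundance are dropped.

    Returns
    -------
    (graph, p~) :
        Aggregated directed graph with ``weight`` edge attributes and the
        per-group abundance series.  Node attribute ``"ab"`` is set.
    """
    nodes = list(graph.nodes)
    missing = [n for n in nodes if n not in partition]
    if missing:
        raise MetanetworkError(f"partition does not cover node(s) {missing}")
    if abundances is None:
        logger.info("aggregating without abundances: uniform p_k = 1/%d", len(nodes))
        p = _uniform_abundance(graph)
    else:
        p = pd.Series(abundances, dtype=float).reindex(nodes)
        if p.isna().any():
            raise MetanetworkError("abundance vector does not cover all graph nodes")

    part = pd.Series({n: partition[n] for n in nodes})
    p_grp = p.groupby(part).sum()
    keep = p_grp[p_grp > 0]
    agg = nx.DiGraph()
    for q, pq in keep.items():
        agg.add_node(q, **{AB: float(pq)})

    # pi~ via grouped bilinear form: numerator M[q,l] = sum pi p_k p_k'
    idx = {n: i for i, n in enumerate(nodes)}
    groups = list(keep.index)
    gidx = {q: i for i, q in enumerate(groups)}
    pv = p.to_numpy()
    num = np.zeros((len(groups), len(groups)))
    for u, v, d in graph.edges(data=True):
        qu, qv = part[u], part[v]
        if qu in gidx and qv in gidx:
            num[gidx[qu], gidx[qv]] += d.get("weight", 1.0) * pv[idx[u]] * pv[idx[v]]
    den = np.outer(keep.to_numpy(), keep.to_numpy())
    pi = num / den
    for i, q in enumerate(groups):
        for j, l in enumerate(groups):
            if pi[i, j] > 0:
                agg.add_edge(q, l, weight=float(pi[i, j]))
    return agg, keep


def append_agg_nets(metanet: Metanetwork) -> Metanetwork:
    """Compute and store aggregated networks at every coarser resolution.

    For each resolution of the trophic table beyond the finest, the metaweb
    (with uniform node weights) and every local network (with its own
    abundances) are aggregated.  Idempotent: repeated calls recompute the
    same objects.
    """
    if metanet.trophic_table is None:
        raise MetanetworkError("append_agg_nets needs a trophic table with >= 2 resolutions")
    table = metanet.trophic_table
    for res in table.coarser_resolutions:
        part = table.partition(res).to_dict()
        nets: dict[str, LocalNetwork] = {}
        g, p = aggregate_network(metanet.metaweb.graph, None, part)
        nets[METAWEB] = LocalNetwork(METAWEB, g, p)
        for name, ln in metanet.locals.items():
            g, p = aggregate_network(ln.graph, ln.abundances, part)
            nets[name] = LocalNetwork(name, g, p)
        metanet.aggregated[res] = nets
    return metanet
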