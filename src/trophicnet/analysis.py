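"""Network comparison: difference networks, metrics, Hill-number diversity.

Difference networks compare two local communities on the metaweb scaffold:
the metaweb subgraph induced by the union of the two node sets, annotated
with signed abundance and edge-weight differences and a presence category
per node.

Diversity uses Hill numbers (effective numbers of order q): q=0 is
richness, q=1 the exponential of Shannon entropy, larger q weights common
nodes/links more.  Node diversity acts on the abundance distribution, link
diversity on the normalised link-strength distribution
``L_kl = pi_kl p_k p_l / sum(...)``.  Pairwise network dissimilarity comes
from the multiplicative alpha/beta/gamma decomposition of Hill numbers
for two equally weighted networks, normalised onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import AB, TL, LocalNetwork, METAWEB, Metanetwork, MetanetworkError

__all__ = [
    "DiffNetwork",
    "diff_networks",
    "compute_metrics",
    "node_diversity",
    "link_diversity",
    "compute_div",
    "compute_dis",
]


# ---------------------------------------------------------------------------
# Difference networks
# ---------------------------------------------------------------------------


@dataclass
class DiffNetwork:
    """Signed difference between two local networks on the metaweb.

    ``graph`` is the metaweb subgraph induced by ``V1 | V2``; node
    attributes carry ``delta_ab = p1 - p2`` (absent nodes count 0) and
    ``category`` in {"both", "only-first", "only-second"}; edges carry
    ``delta_w`` (weights 0 where an endpoint is absent from a network).
    """

    name1: str
    name2: str
    graph: nx.DiGraph

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"node": n, "delta_ab": d["delta_ab"], "category": d["category"]}
            for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows)


def diff_networks(metanet: Metanetwork, name1: str, name2: str) -> DiffNetwork:
    """Build the difference network between two local networks."""
    n1 = metanet.get_network(name1)
    n2 = metanet.get_network(name2)
    v1, v2 = set(n1.graph.nodes), set(n2.graph.nodes)
    g = metanet.metaweb.graph.subgraph(v1 | v2).copy()
    for n in g.nodes:
        p1 = float(n1.abundances.get(n, 0.0))
        p2 = float(n2.abundances.get(n, 0.0))
        cat = "both" if (n in v1 and n in v2) else ("only-first" if n in v1 else "only-second")
        g.nodes[n]["delta_ab"] = p1 - p2
        g.nodes[n]["category"] = cat
    for u, v, d in g.edges(data=True):
        w1 = n1.graph[u][v]["weight"] if n1.graph.has_edge(u, v) else 0.0
        w2 = n2.graph[u][v]["weight"] if n2.graph.has_edge(u, v) else 0.0
        d["delta_w"] = w1 - w2
    return DiffNetwork(name1=name1, name2=name2, graph=g)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _mean_shortest_path(g: nx.DiGraph) -> float:
    """Mean directed unweighted shortest path over reachable ordered pairs.

    Unreachable pairs are excluded, which keeps the metric defined on
    disconnected local networks; NaN when no pair is reachable.
    """
    total, count = 0, 0
    for src, dists in nx.shortest_path_length(g):
        for dst, d in dists.items():
            if dst != src:
                total += d
                count += 1
    return total / count if count else float("nan")


def compute_metrics(metanet: Metanetwork, resolution: str | None = None) -> pd.DataFrame:
    """Mean/max trophic level and mean shortest path per network."""
    rows = []
    for name in metanet.network_names():
        net = metanet.get_network(name, resolution)
        tl = nx.get_node_attributes(net.graph, TL)
        if not tl:
            raise MetanetworkError("trophic levels absent; run compute_TL first")
        vals = np.array(list(tl.values()))
        rows.append(
            {
                "network": name,
                "mean_TL": float(vals.mean()),
                "max_TL": float(vals.max()),
                "mean_shortest_path": _mean_shortest_path(net.graph),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hill-number diversity
# ---------------------------------------------------------------------------


def _hill(p: np.ndarray, q: float) -> float:
    """Hill number of order q of a (renormalised) distribution."""
    p = p[p > 0]
    p = p / p.sum()
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def node_diversity(p, q: float = 1.0) -> float:
    """Hill diversity of order q of a node-abundance vector.

    ``(sum p_k^q)^(1/(1-q))``, with the Shannon limit ``exp(-sum p ln p)``
    at q=1.  The vector is renormalised internally; q=0 counts positive
    entries, uniform abundances over n nodes give n for every q.
    """
    if q < 0:
        raise MetanetworkError("viewpoint q must be >= 0")
    arr = np.asarray(pd.Series(p, dtype=float))
    if (arr < 0).any():
        raise MetanetworkError("abundances must be non-negative")
    if arr.sum() <= 0:
        raise MetanetworkError("all-zero abundance vector has no diversity")
    return _hill(arr, q)


def _link_distribution(graph: nx.DiGraph, p: pd.Series) -> pd.Series:
    """Normalised link strengths L_kl = pi_kl p_k p_l, indexed by edge."""
    rows = {}
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0) * p.get(u, 0.0) * p.get(v, 0.0)
        if w > 0:
            rows[(u, v)] = w
    if not rows:
        raise MetanetworkError("no positive links between positive-abundance nodes")
    s = pd.Series(rows, dtype=float)
    return s / s.sum()


def link_diversity(graph: nx.DiGraph, p, q: float = 1.0) -> float:
    """Hill diversity of order q of the link distribution.

    Links are weighted by ``pi_kl p_k p_l`` and renormalised; m links of
    equal strength give diversity m.
    """
    if q < 0:
        raise MetanetworkError("viewpoint q must be >= 0")
    pser = pd.Series(p, dtype=float)
    return _hill(_link_distribution(graph, pser).to_numpy(), q)


def compute_div(
    metanet: Metanetwork, q: float = 1.0, resolution: str | None = None
) -> pd.DataFrame:
    """Node and link diversity per network at one resolution.

    The metaweb row uses uniform node weights unless an abundance row by
    that name exists.  Link diversity is NaN for edgeless networks.
    """
    rows = []
    for name in metanet.network_names():
        net = metanet.get_network(name, resolution)
        nd = node_diversity(net.abundances, q)
        try:
            ld = link_diversity(net.graph, net.abundances, q)
        except MetanetworkError:
            ld = float("nan")
        rows.append({"network": name, "node_diversity": nd, "link_diversity": ld})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairwise dissimilarity (alpha/beta/gamma Hill decomposition)
# ---------------------------------------------------------------------------


def _beta_dissimilarity(p1: pd.Series, p2: pd.Series, q: float) -> float:
    """Normalised beta dissimilarity of two equally weighted distributions.

    D_gamma is the Hill number of the pooled half/half mixture, D_alpha
    the Hill mean within networks, D_beta = D_gamma / D_alpha in [1, 2].
    Normalisation onto [0, 1]: ln(D_beta)/ln(2) at q=1, otherwise the
    overlap complement (1 - D_beta^(1-q)) / (1 - 2^(1-q)), whose q->1
    limit matches.
    """
    union = sorted(set(p1.index) | set(p2.index))
    a1 = p1.reindex(union).fillna(0.0).to_numpy()
    a2 = p2.reindex(union).fillna(0.0).to_numpy()
    a1, a2 = a1 / a1.sum(), a2 / a2.sum()
    mix = 0.5 * a1 + 0.5 * a2
    d_gamma = _hill(mix, q)
    if abs(q - 1.0) < 1e-12:
        d_alpha = float(np.exp(0.5 * np.log(_hill(a1, 1.0)) + 0.5 * np.log(_hill(a2, 1.0))))
        d_beta = d_gamma / d_alpha
        return float(np.log(d_beta) / np.log(2.0))
    stacked = np.concatenate([0.5 * a1, 0.5 * a2])
    stacked = stacked[stacked > 0]
    d_alpha = 0.5 * float(np.sum(stacked**q) ** (1.0 / (1.0 - q)))
    d_beta = d_gamma / d_alpha
    return float((1.0 - d_beta ** (1.0 - q)) / (1.0 - 2.0 ** (1.0 - q)))


def compute_dis(
    metanet: Metanetwork, q: float = 1.0, resolution: str | None = None
) -> dict[str, pd.DataFrame]:
    """Pairwise node and link dissimilarity matrices between local networks.

    Returns ``{"nodes": D, "links": D}`` — symmetric matrices with zero
    diagonal, entries in [0, 1]: 0 for identical assemblages, 1 for fully
    distinct ones.  Link dissimilarity is NaN for a pair when either
    network has no positive links.
    """
    names = list(metanet.locals)
    if len(names) < 2:
        raise MetanetworkError("pairwise dissimilarity needs at least 2 local networks")
    nets = {n: metanet.get_network(n, resolution) for n in names}
    node_d = pd.DataFrame(0.0, index=names, columns=names)
    link_d = pd.DataFrame(0.0, index=names, columns=names)
    links = {}
    for n, net in nets.items():
        try:
            links[n] = _link_distribution(net.graph, net.abundances)
        except MetanetworkError:
            links[n] = None
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = _beta_dissimilarity(nets[a].abundances, nets[b].abundances, q)
            node_d.loc[a, b] = node_d.loc[b, a] = d
            if links[a] is None or links[b] is None:
                link_d.loc[a, b] = link_d.loc[b, a] = float("nan")
            else:
                d = _beta_dissimilarity(links[a], links[b], q)
                link_d.loc[a, b] = link_d.loc[b, a] = d
    return {"nodes": node_d, "links": link_d}
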