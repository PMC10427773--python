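"""Trophic levels from the symmetrised graph Laplacian.

For a directed network with adjacency ``A``, the trophic level vector ``x``
solves ``L x = v`` where ``L = D - A - A^T`` is the Laplacian of the
symmetrised graph (``D`` the diagonal of total degrees) and
``v = indegree - outdegree`` the imbalance vector.  On a connected network
the solution is unique up to translation; the minimum is pinned to zero so
basal species (no resources) sit at level 0.  A chain a->b->c solves to
levels (0, 1, 2).

Local networks may be disconnected: each weakly connected component is
solved separately and translated so that its minimal-level node sits at
that node's metaweb trophic level, which keeps all networks on the shared
metaweb scale.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .core import TL, LocalNetwork, Metanetwork, MetanetworkError, METAWEB

logger = logging.getLogger("trophicnet")

__all__ = [
    "laplacian_sym",
    "imbalance_vector",
    "solve_trophic_levels",
    "compute_TL",
    "trophic_levels_frame",
]

#: residual bound asserted on every solve
RESIDUAL_TOL = 1e-8


def _adjacency(graph: nx.DiGraph, weighted: bool) -> np.ndarray:
    w = "weight" if weighted else None
    return nx.to_numpy_array(graph, nodelist=list(graph.nodes), weight=w)


def laplacian_sym(graph: nx.DiGraph, weighted: bool = False) -> np.ndarray:
    """Laplacian ``L = D - A - A^T`` of the symmetrised graph.

    ``D`` is the diagonal of row sums of ``A + A^T``.  ``L`` is symmetric
    positive semi-definite with zero row sums; its rank is ``n`` minus the
    number of weakly connected components.  By default the adjacency is
    binary (degree counts); ``weighted=True`` uses edge weights instead.
    """
    if graph.number_of_nodes() == 0:
        raise MetanetworkError("empty graph has no Laplacian")
    a = _adjacency(graph, weighted)
    s = a + a.T
    return np.diag(s.sum(axis=1)) - s


def imbalance_vector(graph: nx.DiGraph, weighted: bool = False) -> np.ndarray:
    """Imbalance ``v = indegree - outdegree`` per node; sums to zero."""
    a = _adjacency(graph, weighted)
    return a.sum(axis=0) - a.sum(axis=1)


def solve_trophic_levels(L: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Solve the singular system ``L x = v`` for one connected component.

    Uses minimum-norm least squares (the system is rank n-1; ``v`` lies in
    the column space), then translates so ``min(x) = 0``.  The residual is
    asserted below 1e-8 as a defensive check.
    """
    if L.shape[0] == 1:
        return np.zeros(1)
    x, *_ = np.linalg.lstsq(L, v, rcond=None)
    resid = np.max(np.abs(L @ x - v))
    if resid > RESIDUAL_TOL:
        raise MetanetworkError(
            f"trophic-level system inconsistent (residual {resid:.2e}); "
            "is the component connected?"
        )
    return x - x.min()


def _component_levels(graph: nx.DiGraph, weighted: bool) -> pd.Series:
    """Levels of a single weakly connected graph, min pinned to 0."""
    nodes = list(graph.nodes)
    L = laplacian_sym(graph, weighted)
    v = imbalance_vector(graph, weighted)
    return pd.Series(solve_trophic_levels(L, v), index=nodes)


def _anchor_node(levels: pd.Series, metaweb_tl: pd.Series) -> str:
    """Node carrying the component's minimal level.

    Ties go to the smallest metaweb trophic level, then node-name order,
    so the anchoring is deterministic.
    """
    eps = 1e-12
    cand = levels.index[levels <= levels.min() + eps]
    return sorted(cand, key=lambda n: (metaweb_tl[n], str(n)))[0]


def compute_TL(metanet: Metanetwork, weighted: bool = False) -> Metanetwork:
    """Attach trophic levels to every network at every present resolution.

    The metaweb (connected by construction) is solved first with its
    minimum at 0.  Each local network is solved per weakly connected
    component; every component is translated so its minimal-level node
    matches that node's metaweb trophic level.  The same procedure runs on
    aggregated networks, anchored to the aggregated metaweb.  Levels are
    stored under the ``"TL"`` node attribute.
    """
    if weighted and metanet.metaweb.is_weighted():
        logger.info("computing trophic levels with edge-weighted degrees")
    _compute_tl_level(metanet.metaweb.graph, metanet.locals, weighted)
    for res, nets in metanet.aggregated.items():
        meta = nets[METAWEB]
        others = {k: v for k, v in nets.items() if k != METAWEB}
        _compute_tl_level(meta.graph, others, weighted)
    return metanet


def _compute_tl_level(
    metaweb_graph: nx.DiGraph, locals_: dict[str, LocalNetwork], weighted: bool
) -> None:
    meta_tl = _component_levels(metaweb_graph, weighted)
    nx.set_node_attributes(metaweb_graph, meta_tl.to_dict(), TL)
    for ln in locals_.values():
        out: dict[str, float] = {}
        for comp in nx.weakly_connected_components(ln.graph):
            sub = ln.graph.subgraph(comp)
            lv = _component_levels(sub, weighted)
            anchor = _anchor_node(lv, meta_tl)
            lv = lv - lv[anchor] + meta_tl[anchor]
            out.update(lv.to_dict())
        nx.set_node_attributes(ln.graph, out, TL)


def trophic_levels_frame(metanet: Metanetwork, resolution: str | None = None) -> pd.DataFrame:
    """Long-format table ``network, node, trophic_level`` for export."""
    rows = []
    for name in metanet.network_names():
        net = metanet.get_network(name, resolution)
        tl = nx.get_node_attributes(net.graph, TL)
        if not tl:
            raise MetanetworkError("trophic levels absent; run compute_TL first")
        for node, x in tl.items():
            rows.append({"network": name, "node": node, "trophic_level": x})
    return pd.DataFrame(rows)
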