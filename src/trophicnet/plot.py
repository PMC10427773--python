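"""Static matplotlib visualisation of metanetworks and difference networks.

Nodes sit at stored layout coordinates (x = trophic level, y = embedded
channel coordinate), node size scales with abundance, node colour follows
the trophic-table group, edge width scales with weight.  Difference plots
use a fixed colour code: red for positive differences (higher in the first
network), blue for negative, grey for zero, with presence categories
marked by shape.  Plots are artifacts of computation, never inputs to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .analysis import DiffNetwork
from .core import AB, Metanetwork, MetanetworkError

__all__ = ["PlotSpec", "plot_static", "plot_diff", "DIFF_COLOURS"]

#: fixed colour code of difference plots
DIFF_COLOURS = {"positive": "#c0392b", "negative": "#2980b9", "zero": "#95a5a6"}
#: marker per presence category
DIFF_MARKERS = {"both": "o", "only-first": "^", "only-second": "v"}


@dataclass(frozen=True)
class PlotSpec:
    """What to draw and how.

    ``layout_key`` is a stored ``(network, resolution, beta)`` key;
    ``flip_coords`` swaps x and y (trophic level vertical, as often
    preferred for large webs).
    """

    network: str = "metaweb"
    resolution: str | None = None
    beta: float | None = None
    colour_by: str | None = None  # trophic-table resolution used for colours
    legend: bool = True
    flip_coords: bool = False
    node_scale: float = 2000.0
    edge_scale: float = 2.0


def _layout_for(metanet: Metanetwork, spec: PlotSpec) -> pd.DataFrame:
    res = spec.resolution or metanet.finest_resolution
    keys = [
        k
        for k in metanet.layouts
        if k[0] == spec.network and k[1] == res and (spec.beta is None or k[2] == spec.beta)
    ]
    if not keys:
        raise MetanetworkError(
            f"no stored layout for network={spec.network!r}, resolution={res!r}, "
            f"beta={spec.beta}; run attach_layout first"
        )
    return metanet.layouts[sorted(keys, key=lambda k: k[2])[0]]


def plot_static(metanet: Metanetwork, spec: PlotSpec, path: str | Path) -> Path:
    """Scatter a network at its stored layout coordinates; write PNG/SVG."""
    coords = _layout_for(metanet, spec)
    net = metanet.get_network(spec.network, spec.resolution)
    nodes = [n for n in net.graph.nodes if n in coords.index]
    xy = coords.loc[nodes, ["x", "y"]].to_numpy(dtype=float)
    if spec.flip_coords:
        xy = xy[:, ::-1]
    ab = np.array([net.graph.nodes[n].get(AB, 1.0) for n in nodes], dtype=float)
    sizes = spec.node_scale * ab / ab.max()

    colours, legend_handles = None, []
    if spec.colour_by and metanet.trophic_table is not None:
        part = metanet.trophic_table.partition(spec.colour_by)
        groups = sorted({part.get(n, str(n)) for n in nodes})
        cmap = plt.get_cmap("tab20")
        gc = {g: cmap(i % 20) for i, g in enumerate(groups)}
        colours = [gc[part.get(n, str(n))] for n in nodes]
        legend_handles = [plt.Line2D([], [], marker="o", ls="", color=gc[g], label=g) for g in groups]

    fig, ax = plt.subplots(figsize=(7, 5))
    pos = {n: tuple(p) for n, p in zip(nodes, xy)}
    for u, v, d in net.graph.edges(data=True):
        if u in pos and v in pos:
            ax.annotate(
                "",
                xy=pos[v],
                xytext=pos[u],
                arrowprops=dict(
                    arrowstyle="-|>",
                    lw=spec.edge_scale * d.get("weight", 1.0),
                    color="0.6",
                    alpha=0.6,
                ),
            )
    ax.scatter(xy[:, 0], xy[:, 1], s=sizes, c=colours, zorder=3)
    for n, p in pos.items():
        ax.annotate(str(n), p, fontsize=7, ha="center", va="bottom", xytext=(0, 4), textcoords="offset points")
    ax.set_xlabel("y" if spec.flip_coords else "trophic level")
    ax.set_ylabel("trophic level" if spec.flip_coords else "y")
    ax.set_title(f"{spec.network} (beta={spec.beta})" if spec.beta else spec.network)
    if spec.legend and legend_handles:
        ax.legend(handles=legend_handles, fontsize=7, loc="best")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_diff(
    diff: DiffNetwork, coords: pd.DataFrame, path: str | Path, legend: bool = True
) -> Path:
    """Draw a difference network with the signed colour code.

    ``coords`` gives (x, y) per node of the difference graph (typically a
    metaweb layout restricted to the union node set).  Node colour encodes
    the sign of the abundance difference, marker the presence category,
    edge colour the sign of the weight difference.
    """
    g = diff.graph
    missing = [n for n in g.nodes if n not in coords.index]
    if missing:
        raise MetanetworkError(f"coordinates missing for nodes {missing}")
    pos = {n: (coords.loc[n, "x"], coords.loc[n, "y"]) for n in g.nodes}

    def sign(v: float) -> str:
        return "positive" if v > 0 else ("negative" if v < 0 else "zero")

    fig, ax = plt.subplots(figsize=(7, 5))
    for u, v, d in g.edges(data=True):
        ax.annotate(
            "",
            xy=pos[v],
            xytext=pos[u],
            arrowprops=dict(arrowstyle="-|>", lw=1.2, color=DIFF_COLOURS[sign(d["delta_w"])], alpha=0.6),
        )
    cats_present = []
    for cat, marker in DIFF_MARKERS.items():
        nodes = [n for n, d in g.nodes(data=True) if d["category"] == cat]
        if not nodes:
            continue
        cats_present.append(cat)
        cols = [DIFF_COLOURS[sign(g.nodes[n]["delta_ab"])] for n in nodes]
        ax.scatter(
            [pos[n][0] for n in nodes],
            [pos[n][1] for n in nodes],
            c=cols,
            marker=marker,
            s=120,
            zorder=3,
            label=cat,
        )
    for n, p in pos.items():
        ax.annotate(str(n), p, fontsize=7, ha="center", va="bottom", xytext=(0, 5), textcoords="offset points")
    ax.set_xlabel("trophic level")
    ax.set_ylabel("y")
    ax.set_title(f"{diff.name1} vs {diff.name2}")
    if legend:
        ax.legend(title="presence", fontsize=7)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
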