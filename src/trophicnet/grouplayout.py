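"""Two-stage "group-TL-tsne" layout for large networks.

Constrained t-SNE cost grows with the node count, so for big webs the
embedding runs only on an aggregated (group-level) network, and the
members of each group are then placed around their group's coordinate by
a seeded force-directed (Fruchterman-Reingold) layout of the group's
internal subgraph.  Each group cloud is centred so its centroid equals the
group's embedded coordinate and rescaled so no member is farther than
``group_diameter / 2`` from that centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import TL, Metanetwork, MetanetworkError
from .layout import Layout, LayoutConfig, _embed_components

__all__ = ["GroupLayoutConfig", "group_tl_tsne", "attach_group_layout"]


@dataclass(frozen=True)
class GroupLayoutConfig:
    """Settings of the two-stage layout.

    ``group_diameter`` is the maximum extent of a group cloud in layout
    coordinate units (a per-group dict or one scalar for all groups).
    ``pin_trophic_levels`` re-pins each node's x to its own trophic level
    after centring (otherwise the group centre carries the aggregated
    level and members spread around it in both axes).
    """

    tsne: LayoutConfig = field(default_factory=LayoutConfig)
    group_diameter: float | dict = 1.0
    force_iterations: int = 50
    seed: int = 0
    pin_trophic_levels: bool = False

    def diameter_of(self, group: str) -> float:
        d = (
            self.group_diameter.get(group, 1.0)
            if isinstance(self.group_diameter, dict)
            else self.group_diameter
        )
        if d <= 0:
            raise MetanetworkError(f"group diameter must be > 0 (group {group!r})")
        return float(d)


def group_tl_tsne(
    metanet: Metanetwork,
    network: str,
    resolution: str,
    config: GroupLayoutConfig | None = None,
) -> Layout:
    """Layout of the finest-resolution network via its aggregated version.

    Runs TL-tsne on the aggregated network at ``resolution`` (stage 1),
    then places each group's members with a seeded Fruchterman-Reingold
    layout of the group's vertex-induced subgraph, centred at the group's
    embedded coordinate and scaled to the configured diameter (stage 2).
    Singleton groups sit exactly at their group coordinate.
    """
    config = config or GroupLayoutConfig()
    if metanet.trophic_table is None or resolution not in metanet.aggregated:
        raise MetanetworkError(
            f"aggregated networks at {resolution!r} not available; "
            "run append_agg_nets before group_tl_tsne"
        )
    agg = metanet.get_network(network, resolution)
    agg_tl = pd.Series(nx.get_node_attributes(agg.graph, TL))
    if len(agg_tl) != agg.graph.number_of_nodes():
        raise MetanetworkError("trophic levels missing on aggregated network; run compute_TL")
    stage1 = _embed_components(agg.graph, agg_tl, config.tsne)

    fine = metanet.get_network(network, metanet.finest_resolution)
    part = metanet.trophic_table.partition(resolution)
    fine_tl = nx.get_node_attributes(fine.graph, TL)

    frames = []
    for gi, group in enumerate(stage1.nodes):
        members = [n for n in fine.graph.nodes if part[n] == group]
        cx, cy = stage1.coords.loc[group, ["x", "y"]]
        if len(members) == 1:
            frames.append(pd.DataFrame({"x": [cx], "y": [cy]}, index=members))
            continue
        sub = fine.graph.subgraph(members)
        pos = nx.spring_layout(
            sub, iterations=config.force_iterations, seed=config.seed + gi
        )
        pts = np.array([pos[m] for m in members], dtype=float)
        pts -= pts.mean(axis=0)  # centroid to origin
        rmax = float(np.max(np.linalg.norm(pts, axis=1)))
        radius = config.diameter_of(group) / 2.0
        if rmax > 0:
            pts *= radius / rmax  # cloud extent = configured diameter
        pts += np.array([cx, cy])
        frames.append(pd.DataFrame(pts, columns=["x", "y"], index=members))
    coords = pd.concat(frames).reindex(list(fine.graph.nodes))
    if coords["x"].isna().any():
        lost = list(coords.index[coords["x"].isna()])
        raise MetanetworkError(f"nodes missing from aggregated layout groups: {lost}")
    if config.pin_trophic_levels:
        coords["x"] = [fine_tl[n] for n in coords.index]
    return Layout(
        coords=coords,
        beta=config.tsne.beta,
        kl_initial=stage1.kl_initial,
        kl_final=stage1.kl_final,
        n_iter=stage1.n_iter,
    )


def attach_group_layout(
    metanet: Metanetwork,
    network: str,
    resolution: str,
    config: GroupLayoutConfig | None = None,
) -> Metanetwork:
    """Store a group-TL-tsne layout under the finest resolution key.

    The resolution field of the key records ``"group-TL-tsne@<resolution>"``
    so group layouts and plain layouts of the same network coexist.
    """
    config = config or GroupLayoutConfig()
    lay = group_tl_tsne(metanet, network, resolution, config)
    metanet.layouts[(network, f"group-TL-tsne@{resolution}", config.tsne.beta)] = lay.coords
    return metanet
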