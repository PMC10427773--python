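"""Synthetic metaweb and metanetwork generators.

These generators provide self-contained study systems:

* :func:`make_pyramid` — an idealised, strongly hierarchical web where
  every node of one layer preys on every node of the layer below; the
  classic shape on which trophic layouts are easiest to read.
* :func:`make_two_branch` — one basal resource feeding two disjoint
  chains (energetic channels) that rejoin at a single top consumer; the
  minimal system with channel structure.
* :func:`make_random_metanetwork` — a random DAG metaweb at a target
  connectance, with Dirichlet-sampled local communities and optionally a
  random nested trophic table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AbundanceTable,
    Metanetwork,
    MetanetworkError,
    Metaweb,
    TrophicTable,
    build_metanet,
)

__all__ = ["make_pyramid", "make_two_branch", "FixtureSpec", "make_random_metanetwork"]


def make_pyramid(layer_sizes: list[int]) -> Metaweb:
    """Layered pyramid web: layer t preys on every node of layer t-1.

    Nodes are named ``L<t>_<i>``; the basal layer has in-degree 0 and all
    trophic levels are exactly the layer indices.
    """
    if len(layer_sizes) < 2 or any(s < 1 for s in layer_sizes):
        raise MetanetworkError("pyramid needs >= 2 layers of positive size")
    layers = [[f"L{t}_{i}" for i in range(s)] for t, s in enumerate(layer_sizes)]
    edges = [
        (prey, pred)
        for lower, upper in zip(layers[:-1], layers[1:])
        for prey in lower
        for pred in upper
    ]
    return Metaweb(edges)


def make_two_branch(chain_length: int = 2) -> Metaweb:
    """One basal node feeding two disjoint chains joined at one apex.

    ``basal -> a1 -> ... -> a<chain_length> -> top`` and the same through
    ``b1..b<chain_length>``: 2*chain_length + 2 nodes.  The two branches
    are exchangeable by symmetry, so same-rank branch nodes share trophic
    levels while belonging to different energetic channels.
    """
    if chain_length < 1:
        raise MetanetworkError("chain_length must be >= 1")
    edges = []
    for branch in ("a", "b"):
        chain = ["basal"] + [f"{branch}{i}" for i in range(1, chain_length + 1)] + ["top"]
        edges += list(zip(chain[:-1], chain[1:]))
    return Metaweb(edges)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the random metanetwork generator.

    ``connectance`` is the expected edge density over ordered node pairs
    of a DAG (upper triangle of a random node order).  ``n_communities``
    abundance rows are drawn from a symmetric Dirichlet and sparsified by
    zeroing each entry independently with probability ``zero_prob``.
    ``group_sizes`` optionally requests a random nested trophic table with
    the given number of groups per coarser resolution (fine -> coarse).
    """

    n_nodes: int = 50
    connectance: float = 0.15
    n_communities: int = 5
    zero_prob: float = 0.3
    dirichlet_alpha: float = 1.0
    group_sizes: tuple[int, ...] = ()
    seed: int = 0
    max_tries: int = 200


def _random_connected_dag(
    rng: np.random.Generator, spec: FixtureSpec
) -> tuple[Metaweb, list[str]]:
    """Returns the metaweb plus the node order of the DAG (basal first)."""
    names = [f"n{i:03d}" for i in range(spec.n_nodes)]
    for _ in range(spec.max_tries):
        order = rng.permutation(spec.n_nodes)
        mask = rng.random((spec.n_nodes, spec.n_nodes)) < spec.connectance
        edges = [
            (names[order[i]], names[order[j]])
            for i in range(spec.n_nodes)
            for j in range(i + 1, spec.n_nodes)
            if mask[i, j]
        ]
        if not edges:
            continue
        try:
            return Metaweb(edges, nodes=names), [names[i] for i in order]
        except MetanetworkError:
            continue  # disconnected draw: resample
    raise MetanetworkError(
        "could not draw a weakly connected metaweb; raise connectance or max_tries"
    )


def make_random_metanetwork(spec: FixtureSpec) -> Metanetwork:
    """Random metanetwork: DAG metaweb + Dirichlet communities (+ table).

    Deterministic for a given ``spec.seed``.  Every abundance row is
    guaranteed at least one positive entry (zero-masking is redrawn
    otherwise).
    """
    rng = np.random.default_rng(spec.seed)
    mw, dag_order = _random_connected_dag(rng, spec)
    names = mw.nodes
    rows = {}
    for c in range(spec.n_communities):
        for _ in range(spec.max_tries):
            p = rng.dirichlet([spec.dirichlet_alpha] * len(names))
            p = np.where(rng.random(len(names)) < spec.zero_prob, 0.0, p)
            if p.sum() > 0:
                break
        rows[f"community_{c}"] = p
    ab = AbundanceTable(pd.DataFrame.from_dict(rows, orient="index", columns=names))

    table = None
    if spec.group_sizes:
        # groups mimic functional guilds: contiguous blocks of the DAG order,
        # so they are trophically coherent (a uniformly random grouping links
        # every group to every other and degenerates all aggregated levels)
        mapping = pd.DataFrame(index=pd.Index(names, name="nodes"))
        block_of = pd.Series(range(len(dag_order)), index=dag_order)
        prev_groups = len(names)
        for r, n_groups in enumerate(spec.group_sizes):
            if n_groups >= prev_groups:
                raise MetanetworkError("group counts must strictly decrease fine -> coarse")
            cuts = np.sort(rng.choice(np.arange(1, prev_groups), size=n_groups - 1,
                                      replace=False))
            block_of = pd.Series(np.searchsorted(cuts, block_of, side="right"),
                                 index=block_of.index)
            mapping[f"resolution_{r + 1}"] = [
                f"r{r + 1}_g{block_of[n]}" for n in names
            ]
            prev_groups = n_groups
        table = TrophicTable(mapping)
    return build_metanet(mw, ab, table)
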