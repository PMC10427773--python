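import networkx as nx
import numpy as np
import pandas as pd
import pytest

import trophicnet as tn


@pytest.fixture
def chain_metaweb():
    """a -> b -> c; trophic levels (0, 1, 2)."""
    return tn.Metaweb([("a", "b"), ("b", "c")])


@pytest.fixture
def chain4_metaweb():
    """a -> b -> c -> d; used for the per-component anchoring example."""
    return tn.Metaweb([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def pyramid_metanet():
    """Idealised 4-layer pyramid web (layers 4,3,2,1) with trophic levels."""
    mn = tn.build_metanet(tn.make_pyramid([4, 3, 2, 1]))
    tn.compute_TL(mn)
    return mn


@pytest.fixture
def two_branch_metanet():
    """Two 4-node energetic channels sharing one basal node and one apex."""
    mn = tn.build_metanet(tn.make_two_branch(4))
    tn.compute_TL(mn)
    return mn


@pytest.fixture
def small_metanet(chain_metaweb):
    """Chain metaweb with two overlapping communities and a 2-level table."""
    ab = tn.AbundanceTable(
        pd.DataFrame(
            [[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]],
            index=["s1", "s2"],
            columns=["a", "b", "c"],
        )
    )
    tt = tn.TrophicTable(
        pd.DataFrame(
            {"group": ["low", "low", "high"]},
            index=pd.Index(["a", "b", "c"], name="species"),
        )
    )
    return tn.build_metanet(chain_metaweb, ab, tt)


@pytest.fixture
def random_metanet():
    """50-node random metanetwork with 5 communities and a nested table."""
    spec = tn.FixtureSpec(
        n_nodes=50, connectance=0.12, n_communities=5, group_sizes=(8, 3), seed=11
    )
    mn = tn.make_random_metanetwork(spec)
    tn.append_agg_nets(mn)
    tn.compute_TL(mn)
    return mn


def random_weakly_connected_digraph(rng: np.random.Generator, n: int) -> nx.DiGraph:
    """Random digraph, resampled until weakly connected."""
    while True:
        p = max(2.0 / n, rng.uniform(0.02, 0.2))
        m = rng.random((n, n)) < p
        np.fill_diagonal(m, False)
        g = nx.from_numpy_array(m.astype(int), create_using=nx.DiGraph)
        if n == 1 or nx.is_weakly_connected(g):
            return g
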