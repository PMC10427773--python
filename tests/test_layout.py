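"""Diffusion kernel and constrained t-SNE layout behaviour."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.linalg

import trophicnet as tn
from trophicnet.core import TL
from trophicnet.layout import _embed_components


def tl_of(metanet, network="metaweb"):
    return pd.Series(nx.get_node_attributes(metanet.get_network(network).graph, TL))


class TestDiffusionKernel:
    def test_beta_zero_is_identity(self, pyramid_metanet):
        K = tn.diffusion_kernel(pyramid_metanet.metaweb.graph, 0.0)
        assert np.allclose(K, np.eye(K.shape[0]), atol=1e-12)

    def test_two_node_closed_form(self):
        # L eigenvalues {0, 2}: K = [[(1+e^-1)/2, (1-e^-1)/2], ...] at beta=.5
        g = nx.DiGraph([("a", "b")])
        K = tn.diffusion_kernel(g, 0.5)
        hi, lo = (1 + np.exp(-1)) / 2, (1 - np.exp(-1)) / 2
        assert np.allclose(K, [[hi, lo], [lo, hi]], atol=1e-12)

    def test_symmetry_and_row_sums(self, random_metanet):
        K = tn.diffusion_kernel(random_metanet.metaweb.graph, 0.3)
        assert np.allclose(K, K.T, atol=1e-12)
        assert np.allclose(K.sum(axis=1), 1.0, atol=1e-10)

    def test_large_beta_converges_to_uniform(self):
        g = tn.make_pyramid([2, 2, 1]).graph
        K = tn.diffusion_kernel(g, 50.0)
        assert np.allclose(K, 1.0 / 5, atol=1e-8)

    def test_semigroup_against_expm_oracle(self, two_branch_metanet):
        g = two_branch_metanet.metaweb.graph
        L = tn.laplacian_sym(g)
        for b1, b2 in [(0.1, 0.3), (0.5, 0.7)]:
            K1, K2 = tn.diffusion_kernel(g, b1), tn.diffusion_kernel(g, b2)
            K12 = tn.diffusion_kernel(g, b1 + b2)
            assert np.allclose(K1 @ K2, K12, atol=1e-8)
            assert np.allclose(K12, scipy.linalg.expm(-(b1 + b2) * L), atol=1e-8)

    def test_positivity_on_connected_graph(self, pyramid_metanet):
        K = tn.diffusion_kernel(pyramid_metanet.metaweb.graph, 0.2)
        assert (K > 0).all()


class TestAffinities:
    def test_two_node_pair_each_half(self):
        g = nx.DiGraph([("a", "b")])
        P = tn.kernel_to_affinities(tn.diffusion_kernel(g, 0.5))
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert np.all(np.diag(P) == 0)

    def test_identity_kernel_rejected_as_degenerate(self):
        with pytest.raises(tn.MetanetworkError, match="degenerate"):
            tn.kernel_to_affinities(np.eye(3))

    def test_normalisation(self, pyramid_metanet):
        P = tn.kernel_to_affinities(
            tn.diffusion_kernel(pyramid_metanet.metaweb.graph, 0.1)
        )
        assert P.sum() == pytest.approx(1.0, abs=1e-12)
        assert (P >= 0).all()


class TestTlTsne:
    def test_x_pinned_to_trophic_levels_exactly(self, pyramid_metanet):
        tl = tl_of(pyramid_metanet)
        lay = tn.tl_tsne(pyramid_metanet.metaweb.graph, tl,
                         tn.LayoutConfig(beta=0.04, seed=1))
        assert (lay.coords["x"] == tl[lay.nodes]).all()

    def test_two_node_stays_at_seeded_init(self):
        g = nx.DiGraph([("a", "b")])
        tl = pd.Series({"a": 0.0, "b": 1.0})
        cfg = tn.LayoutConfig(beta=0.5, seed=3)
        lay = tn.tl_tsne(g, tl, cfg)
        expected = np.random.default_rng(3).normal(scale=cfg.init_scale, size=2)
        assert np.array_equal(lay.coords["y"].to_numpy(), expected)
        assert lay.kl_final == 0.0

    @pytest.mark.parametrize("beta", [0.04, 0.35])
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_descent_on_pyramid(self, pyramid_metanet, beta, seed):
        tl = tl_of(pyramid_metanet)
        lay = tn.tl_tsne(pyramid_metanet.metaweb.graph, tl,
                         tn.LayoutConfig(beta=beta, seed=seed))
        assert lay.kl_final <= lay.kl_initial

    def test_bit_identical_rerun_with_same_seed(self, pyramid_metanet):
        tl = tl_of(pyramid_metanet)
        cfg = tn.LayoutConfig(beta=0.04, seed=1)
        a = tn.tl_tsne(pyramid_metanet.metaweb.graph, tl, cfg)
        b = tn.tl_tsne(pyramid_metanet.metaweb.graph, tl, cfg)
        assert a.coords.equals(b.coords)
        assert a.kl_final == b.kl_final

    def test_disconnected_graph_embedded_per_component(self, chain4_metaweb):
        ab = tn.AbundanceTable(
            pd.DataFrame([[0.4, 0.3, 0.0, 0.3]], index=["s"],
                         columns=["a", "b", "c", "d"])
        )
        mn = tn.build_metanet(chain4_metaweb, ab)
        tn.compute_TL(mn)
        ln = mn.locals["s"]
        tl = pd.Series(nx.get_node_attributes(ln.graph, TL))
        lay = _embed_components(ln.graph, tl, tn.LayoutConfig(beta=0.1, seed=0))
        assert set(lay.nodes) == {"a", "b", "d"}
        assert lay.coords.loc["d", "y"] == 0.0  # singleton component
        assert lay.coords.loc["d", "x"] == pytest.approx(3.0, abs=1e-9)


class TestChannelSeparation:
    """Two disjoint energy channels share a basal node and an apex; diffusion
    makes same-channel nodes more similar as beta grows, and the layout keeps
    the channels apart in y."""

    GRID = [0.01, 0.1, 0.5, 1.0]

    @staticmethod
    def _branches(g):
        a = [n for n in g.nodes if str(n).startswith("a")]
        b = [n for n in g.nodes if str(n).startswith("b")]
        return a, b

    def test_kernel_between_minus_within_decreases_with_beta(self, two_branch_metanet):
        g = two_branch_metanet.metaweb.graph
        nodes = list(g.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        a, b = self._branches(g)
        seps = []
        for beta in self.GRID:
            K = tn.diffusion_kernel(g, beta)
            within = np.mean(
                [K[idx[u], idx[v]] for grp in (a, b)
                 for u, v in itertools.combinations(grp, 2)]
            )
            between = np.mean([K[idx[u], idx[v]] for u in a for v in b])
            seps.append(between - within)
        assert all(x > y for x, y in zip(seps, seps[1:]))

    def test_layout_keeps_channels_apart(self, two_branch_metanet):
        g = two_branch_metanet.metaweb.graph
        tl = tl_of(two_branch_metanet)
        a, b = self._branches(g)
        for beta in self.GRID:
            seps = []
            for seed in range(1, 6):
                lay = tn.tl_tsne(g, tl, tn.LayoutConfig(beta=beta, seed=seed))
                y = lay.coords["y"]
                within = np.mean(
                    [abs(y[u] - y[v]) for grp in (a, b)
                     for u, v in itertools.combinations(grp, 2)]
                )
                between = np.mean([abs(y[u] - y[v]) for u in a for v in b])
                seps.append(between - within)
            assert np.median(seps) > 0

    def test_branch_swap_permutes_kernel(self, two_branch_metanet):
        """The automorphism exchanging branches leaves the kernel invariant."""
        g = two_branch_metanet.metaweb.graph
        nodes = list(g.nodes)
        import re

        def swapped(n):
            if re.fullmatch(r"a\d+", n):
                return "b" + n[1:]
            if re.fullmatch(r"b\d+", n):
                return "a" + n[1:]
            return n

        swap = {n: swapped(n) for n in nodes}
        K = tn.diffusion_kernel(g, 0.3)
        idx = {n: i for i, n in enumerate(nodes)}
        perm = [idx[swap[n]] for n in nodes]
        assert np.allclose(K, K[np.ix_(perm, perm)], atol=1e-10)


class TestMoran:
    def test_two_node_hand_value(self):
        g = nx.DiGraph([("a", "b")])
        lay = tn.Layout(
            coords=pd.DataFrame({"x": [0, 1], "y": [-1.0, 1.0]}, index=["a", "b"]),
            beta=0.1, kl_initial=0, kl_final=0, n_iter=0,
        )
        assert tn.extended_moran(lay, g) == pytest.approx(-1.0)

    def test_against_double_loop_oracle(self, random_metanet):
        g = random_metanet.metaweb.graph
        nodes = list(g.nodes)
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(nodes))
        lay = tn.Layout(
            coords=pd.DataFrame({"x": 0.0, "y": y}, index=nodes),
            beta=0.1, kl_initial=0, kl_final=0, n_iter=0,
        )
        a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
        w = a + a.T
        ybar = y.mean()
        num = sum(
            w[i, j] * (y[i] - ybar) * (y[j] - ybar)
            for i in range(len(nodes)) for j in range(len(nodes))
        )
        den = sum((yi - ybar) ** 2 for yi in y)
        expected = len(nodes) / w.sum() * num / den
        assert tn.extended_moran(lay, g) == pytest.approx(expected, abs=1e-10)

    def test_constant_layout_rejected(self):
        g = nx.DiGraph([("a", "b")])
        lay = tn.Layout(
            coords=pd.DataFrame({"x": [0, 1], "y": [2.0, 2.0]}, index=["a", "b"]),
            beta=0.1, kl_initial=0, kl_final=0, n_iter=0,
        )
        with pytest.raises(tn.MetanetworkError, match="constant"):
            tn.extended_moran(lay, g)


class TestSelectBeta:
    def test_single_element_grid(self, pyramid_metanet):
        tl = tl_of(pyramid_metanet)
        prof = tn.select_beta(pyramid_metanet.metaweb.graph, tl, [0.2],
                              tn.LayoutConfig(seed=1))
        assert prof.selected_beta == 0.2
        assert len(prof.moran) == 1

    def test_profile_length_and_determinism(self, pyramid_metanet):
        tl = tl_of(pyramid_metanet)
        grid = [0.04, 0.35]
        p1 = tn.select_beta(pyramid_metanet.metaweb.graph, tl, grid,
                            tn.LayoutConfig(seed=1))
        p2 = tn.select_beta(pyramid_metanet.metaweb.graph, tl, grid,
                            tn.LayoutConfig(seed=1))
        assert len(p1.moran) == len(grid)
        assert p1.moran == p2.moran
        assert p1.selected_beta == p2.selected_beta

    def test_empty_or_invalid_grid_rejected(self, pyramid_metanet):
        tl = tl_of(pyramid_metanet)
        with pytest.raises(tn.MetanetworkError):
            tn.select_beta(pyramid_metanet.metaweb.graph, tl, [], tn.LayoutConfig())
        with pytest.raises(tn.MetanetworkError):
            tn.select_beta(pyramid_metanet.metaweb.graph, tl, [-0.1], tn.LayoutConfig())


class TestAttachLayout:
    def test_round_trip_and_multiple_betas(self, pyramid_metanet):
        mn = pyramid_metanet
        tn.attach_layout(mn, "metaweb", tn.LayoutConfig(beta=0.04, seed=1))
        tn.attach_layout(mn, "metaweb", tn.LayoutConfig(beta=0.35, seed=1))
        k1 = ("metaweb", mn.finest_resolution, 0.04)
        k2 = ("metaweb", mn.finest_resolution, 0.35)
        assert k1 in mn.layouts and k2 in mn.layouts
        again = tn.tl_tsne(mn.metaweb.graph, tl_of(mn), tn.LayoutConfig(beta=0.04, seed=1))
        assert mn.layouts[k1].equals(again.coords)

    def test_unknown_network_rejected(self, pyramid_metanet):
        with pytest.raises(tn.MetanetworkError, match="unknown network"):
            tn.attach_layout(pyramid_metanet, "nope", tn.LayoutConfig(beta=0.1))

    def test_missing_trophic_levels_instructive_error(self, chain_metaweb):
        mn = tn.build_metanet(chain_metaweb)
        with pytest.raises(tn.MetanetworkError, match="compute_TL"):
            tn.attach_layout(mn, "metaweb", tn.LayoutConfig(beta=0.1))
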