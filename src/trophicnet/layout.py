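"""Diffusion kernel and the trophic-level-constrained t-SNE layout.

The layout places each node at ``(x, y)`` with ``x`` pinned to its trophic
level and ``y`` chosen by dimension reduction: node similarity in the
"high-dimensional" space is the graph diffusion kernel

    K = exp(-beta * L)

(``L`` the symmetrised Laplacian, ``beta`` the diffusion parameter), and
the low-dimensional similarity is the Student-t kernel of t-SNE.  Gradient
descent minimises the Kullback-Leibler divergence between the two, moving
``y`` only.  Larger ``beta`` diffuses further: nodes sharing energy-flow
paths (channels) grow more similar and are pulled together along ``y``.

Layout quality across ``beta`` values is scored with an extended Moran
index — the spatial autocorrelation of ``y`` over the symmetrised
adjacency — and :func:`select_beta` picks the argmax of that profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .core import AB, TL, Metanetwork, MetanetworkError
from .trophic import laplacian_sym

logger = logging.getLogger("trophicnet")

__all__ = [
    "LayoutConfig",
    "Layout",
    "MoranProfile",
    "diffusion_kernel",
    "kernel_to_affinities",
    "tl_tsne",
    "extended_moran",
    "select_beta",
    "attach_layout",
]


@dataclass(frozen=True)
class LayoutConfig:
    """Hyperparameters of the constrained t-SNE descent.

    Standard t-SNE settings: momentum 0.5 switching to 0.8 at iteration
    250, early exaggeration x4 for the first 100 iterations, adaptive
    per-coordinate gains, y initialised from N(0, init_scale^2).
    ``learning_rate=None`` picks a scale-aware default,
    ``max(1, n / early_exaggeration)``: the affinity matrix is normalised
    globally (not per row as in perplexity-based t-SNE), so gradients
    shrink with node count and a fixed large step oscillates on small
    webs.  ``seed`` is mandatory for reproducibility; descent stops at
    ``max_iter`` or when the KL divergence changes by less than ``tol``
    between iterations.
    """

    beta: float = 0.1
    max_iter: int = 1000
    learning_rate: float | None = None
    momentum_early: float = 0.5
    momentum_late: float = 0.8
    momentum_switch: int = 250
    early_exaggeration: float = 4.0
    exaggeration_iters: int = 100
    init_scale: float = 1e-4
    seed: int = 0
    tol: float = 1e-7
    weighted: bool = False

    def __post_init__(self):
        if self.beta < 0:
            raise MetanetworkError("beta must be positive")
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise MetanetworkError("learning_rate must be positive")
        if self.max_iter < 1 or self.init_scale <= 0:
            raise MetanetworkError("layout hyperparameters must be positive")

    def effective_learning_rate(self, n: int) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return max(1.0, n / self.early_exaggeration)


@dataclass
class Layout:
    """Result of one TL-tsne run: coordinates plus descent diagnostics."""

    coords: pd.DataFrame  # index = nodes, columns = ["x", "y"]
    beta: float
    kl_initial: float
    kl_final: float
    n_iter: int

    @property
    def nodes(self) -> list:
        return list(self.coords.index)


@dataclass
class MoranProfile:
    """Extended-Moran-index profile over a beta grid."""

    betas: list[float]
    moran: list[float | None]
    layouts: dict[float, Layout] = field(default_factory=dict)

    @property
    def selected_beta(self) -> float:
        ok = [(b, m) for b, m in zip(self.betas, self.moran) if m is not None]
        if not ok:
            raise MetanetworkError("no beta value produced a layout")
        best = max(m for _, m in ok)
        return min(b for b, m in ok if m == best)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.betas, "moran_index": self.moran})


# ---------------------------------------------------------------------------
# Diffusion kernel
# ---------------------------------------------------------------------------


def diffusion_kernel(graph: nx.DiGraph, beta: float, weighted: bool = False) -> np.ndarray:
    """Diffusion kernel ``K = exp(-beta L)`` via eigendecomposition.

    ``L = U diag(lam) U^T`` gives ``K = U diag(exp(-beta lam)) U^T``.
    ``K`` is symmetric and doubly stochastic (rows sum to 1, since the
    constant vector is in the null space of ``L``); ``beta = 0`` yields the
    identity.  Node order follows ``graph.nodes``.
    """
    if beta < 0:
        raise MetanetworkError("beta must be >= 0")
    L = laplacian_sym(graph, weighted)
    lam, U = np.linalg.eigh(L)
    K = (U * np.exp(-beta * lam)) @ U.T
    if not np.all(np.isfinite(K)):
        raise MetanetworkError(f"non-finite kernel entries at beta={beta}; try a smaller beta")
    return K


def kernel_to_affinities(K: np.ndarray) -> np.ndarray:
    """Joint similarity matrix for t-SNE from a diffusion kernel.

    Off-diagonal kernel entries are normalised to sum to one; the diagonal
    is zeroed (self-similarity carries no layout information).  The kernel
    is already symmetric, so no symmetrisation step is needed.
    """
    n = K.shape[0]
    if n < 2:
        raise MetanetworkError("affinities need at least 2 nodes")
    P = K.copy()
    np.fill_diagonal(P, 0.0)
    total = P.sum()
    if total <= 0:
        raise MetanetworkError(
            "degenerate affinities: kernel has no off-diagonal mass (beta too small?)"
        )
    return P / total


# ---------------------------------------------------------------------------
# Constrained t-SNE
# ---------------------------------------------------------------------------


def _q_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Student-t similarities over 2-D points; returns (Q, 1/(1+d^2))."""
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    inv = 1.0 / (1.0 + dx**2 + dy**2)
    np.fill_diagonal(inv, 0.0)
    return inv / inv.sum(), inv


def _kl(P: np.ndarray, Q: np.ndarray) -> float:
    mask = P > 0
    q = np.maximum(Q[mask], 1e-300)
    return float(np.sum(P[mask] * np.log(P[mask] / q)))


def tl_tsne(
    graph: nx.DiGraph,
    trophic_levels: pd.Series,
    config: LayoutConfig,
) -> Layout:
    """Embed one connected graph with x fixed to trophic levels.

    The x-coordinates are held at the trophic levels throughout; only y
    moves, following the standard t-SNE gradient restricted to the y
    component, with momentum and early exaggeration.  Deterministic for a
    given ``config.seed``.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n < 2:
        raise MetanetworkError("embedding needs at least 2 nodes")
    x = trophic_levels.reindex(nodes).to_numpy(dtype=float)
    if np.isnan(x).any():
        raise MetanetworkError("trophic levels missing for some nodes; run compute_TL")

    K = diffusion_kernel(graph, config.beta, config.weighted)
    P = kernel_to_affinities(K)

    rng = np.random.default_rng(config.seed)
    y = rng.normal(scale=config.init_scale, size=n)
    vel = np.zeros(n)

    if n == 2:
        # with a single off-diagonal pair both P and Q are forced to 1/2:
        # the objective is constant in y, so the seeded init is already optimal
        coords = pd.DataFrame({"x": x, "y": y}, index=nodes)
        return Layout(coords=coords, beta=config.beta, kl_initial=0.0, kl_final=0.0, n_iter=0)

    Q, _ = _q_matrix(x, y)
    kl_initial = _kl(P, Q)
    kl_prev = kl_initial
    kl = kl_initial
    it = 0
    lr = config.effective_learning_rate(n)
    gains = np.ones(n)
    for it in range(1, config.max_iter + 1):
        Pe = P * config.early_exaggeration if it <= config.exaggeration_iters else P
        Q, inv = _q_matrix(x, y)
        # t-SNE gradient, y component only: 4 * sum_j (p-q) inv_ij (y_i - y_j)
        W = (Pe - Q) * inv
        grad = 4.0 * (W.sum(axis=1) * y - W @ y)
        gains = np.maximum(np.where(np.sign(grad) != np.sign(vel), gains + 0.2, gains * 0.8), 0.01)
        mom = config.momentum_early if it < config.momentum_switch else config.momentum_late
        vel = mom * vel - lr * gains * grad
        y = y + vel
        kl = _kl(P, Q)
        # the descent launches slowly from the near-zero init, so the
        # convergence test only arms once the late-momentum phase starts
        if it > config.momentum_switch and abs(kl - kl_prev) < config.tol:
            break
        kl_prev = kl

    Q, _ = _q_matrix(x, y)
    kl = _kl(P, Q)
    coords = pd.DataFrame({"x": x, "y": y}, index=nodes)
    return Layout(coords=coords, beta=config.beta, kl_initial=kl_initial, kl_final=kl, n_iter=it)


def _embed_components(graph: nx.DiGraph, tl: pd.Series, config: LayoutConfig) -> Layout:
    """Embed each weakly connected component separately.

    The kernel of a disconnected graph is block-diagonal, so cross-
    component affinities vanish and relative placement would be arbitrary;
    embedding per component (singletons at y=0) makes this explicit.
    Components share the x-axis through metaweb-anchored trophic levels.
    """
    comps = list(nx.weakly_connected_components(graph))
    if len(comps) == 1:
        return tl_tsne(graph, tl, config)
    frames, kl0, kl1, iters = [], 0.0, 0.0, 0
    for ci, comp in enumerate(sorted(comps, key=lambda c: sorted(map(str, c)))):
        sub = graph.subgraph(comp)
        if len(comp) == 1:
            node = next(iter(comp))
            frames.append(pd.DataFrame({"x": [tl[node]], "y": [0.0]}, index=[node]))
            continue
        sub_layout = tl_tsne(sub, tl, replace(config, seed=config.seed + ci))
        frames.append(sub_layout.coords)
        kl0 += sub_layout.kl_initial
        kl1 += sub_layout.kl_final
        iters = max(iters, sub_layout.n_iter)
    coords = pd.concat(frames).reindex(list(graph.nodes))
    return Layout(coords=coords, beta=config.beta, kl_initial=kl0, kl_final=kl1, n_iter=iters)


# ---------------------------------------------------------------------------
# Extended Moran index and beta selection
# ---------------------------------------------------------------------------


def extended_moran(layout: Layout, graph: nx.DiGraph, weighted: bool = False) -> float:
    """Moran spatial autocorrelation of the embedded y-coordinate.

    ``I = (n / sum_ij w_ij) * sum_ij w_ij (y_i - ybar)(y_j - ybar)
    / sum_i (y_i - ybar)^2`` with weights ``w = A + A^T`` (symmetrised
    adjacency).  Only y enters: x is pinned to trophic levels, so its
    autocorrelation says nothing about the optimisation.  High values mean
    adjacent nodes sit at similar heights — a coherent channel structure.
    """
    nodes = list(graph.nodes)
    y = layout.coords["y"].reindex(nodes).to_numpy(dtype=float)
    w = "weight" if weighted else None
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=w)
    W = a + a.T
    dev = y - y.mean()
    var = float(dev @ dev)
    if var <= 0:
        raise MetanetworkError("constant layout: Moran index undefined (zero variance in y)")
    n = len(nodes)
    return float(n / W.sum() * (dev @ W @ dev) / var)


def select_beta(
    graph: nx.DiGraph,
    trophic_levels: pd.Series,
    beta_grid: list[float],
    config: LayoutConfig,
) -> MoranProfile:
    """Run TL-tsne over a beta grid and score each layout by Moran index.

    Every beta uses the same seed so profiles are reproducible.  The
    selected beta is the argmax of the profile (ties break to the smallest
    beta).  Per-beta failures are recorded as missing, not raised; the full
    profile is returned so users can explore several beta configurations
    rather than trust a single optimum.
    """
    if not beta_grid:
        raise MetanetworkError("beta grid is empty")
    if any(b <= 0 for b in beta_grid):
        raise MetanetworkError("beta grid values must be > 0")
    moran: list[float | None] = []
    layouts: dict[float, Layout] = {}
    for b in beta_grid:
        try:
            lay = _embed_components(graph, trophic_levels, replace(config, beta=b))
            layouts[b] = lay
            moran.append(extended_moran(lay, graph, config.weighted))
        except MetanetworkError as exc:
            logger.warning("beta=%g failed: %s", b, exc)
            moran.append(None)
    return MoranProfile(betas=list(beta_grid), moran=moran, layouts=layouts)


# ---------------------------------------------------------------------------
# Attachment to the metanetwork store
# ---------------------------------------------------------------------------


def attach_layout(
    metanet: Metanetwork,
    network: str,
    config: LayoutConfig,
    resolution: str | None = None,
) -> Metanetwork:
    """Compute a TL-tsne layout and store it under (network, resolution, beta).

    Multiple beta values coexist in the store; re-attaching an existing key
    overwrites it with a log notice.
    """
    res = resolution or metanet.finest_resolution
    net = metanet.get_network(network, res)
    tl = pd.Series(nx.get_node_attributes(net.graph, TL))
    if len(tl) != net.graph.number_of_nodes():
        raise MetanetworkError("trophic levels missing; run compute_TL before attach_layout")
    lay = _embed_components(net.graph, tl, config)
    key = (network, res, config.beta)
    if key in metanet.layouts:
        logger.info("overwriting existing layout %s", key)
    metanet.layouts[key] = lay.coords
    return metanet


def layout_frame(metanet: Metanetwork) -> pd.DataFrame:
    """Long-format table of all stored layouts for CSV export."""
    rows = []
    for (network, res, beta), coords in metanet.layouts.items():
        for node, r in coords.iterrows():
            rows.append(
                {
                    "network": network,
                    "resolution": res,
                    "beta": beta,
                    "node": node,
                    "x": r["x"],
                    "y": r["y"],
                }
            )
    return pd.DataFrame(rows)
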