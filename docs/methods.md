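# Methods

This note records the models implemented in `trophicnet`, the numerical
choices behind them, and what the synthetic study systems do and do not
establish about real data.

## Data model

A metaweb is a directed graph over named nodes, edges oriented resource →
consumer (direction of energy flow), with non-negative edge weights
(link probabilities or diet fractions; 1 when unweighted). The metaweb
must be weakly connected — a disconnected "regional web" is two study
systems, and the shared trophic-level scale below depends on
connectivity. A reader flag reverses orientation for files encoded
predator → prey. Duplicate edges in input collapse by summing weights
(with a warning); node-name matching is exact and case-sensitive, because
silent fuzzy matching corrupts community matrices.

Abundance rows are rescaled to relative abundances (sum 1) on ingestion;
raw totals are kept as metadata, so biomass tables can be fed directly.
Local networks are vertex-induced subgraphs of the metaweb on the nodes
with positive abundance; they may be disconnected (sampling effects).

## Trophic levels

Levels solve `L x = v` with `L = D − A − Aᵀ` (symmetrised Laplacian) and
`v = indegree − outdegree`. The adjacency is binary by default — the
imbalance vector is a degree difference, so degrees and Laplacian use the
same convention — with an edge-weighted variant behind a flag; its use is
logged when weights are present, since weighted and binary levels differ.

The system is singular (rank n − #components). We solve by minimum-norm
least squares on the full system and then translate so the minimum is 0;
this handles every component size including singletons, and the residual
‖Lx − v‖∞ is asserted ≤ 1e−8 defensively (the imbalance vector always
lies in the column space of a connected component's Laplacian). Pinning
one coordinate and solving the reduced nonsingular system gives the same
answer and is exercised as a test oracle (pseudo-inverse with explicit
rank truncation).

Disconnected local networks are solved per weakly connected component
(weak connectivity, because the symmetrised Laplacian is blind to edge
direction). Each component is translated so its minimal-level node takes
that node's metaweb level. When several nodes tie for the component
minimum (tolerance 1e−12), the anchor is the one with the smallest
metaweb level, ties broken by node name — an arbitrary but deterministic
rule; the choice only shifts a component by the difference between tied
anchors' metaweb levels.

## Diffusion kernel and TL-tsne

The kernel `K = exp(−βL)` is computed through the eigendecomposition of
`L` (dense `eigh`; webs of interest are ≤ a few thousand nodes). `K` is
symmetric and doubly stochastic; β → 0 gives the identity and β → ∞ the
flat 1/n projection on a connected graph. β is in units of inverse
Laplacian eigenvalue — the degree scale of the web — so useful values for
food webs sit roughly in [0.01, 1].

High-dimensional affinities for the embedding are the kernel itself with
zero diagonal, normalised globally over pairs. No perplexity calibration
is used: the kernel already encodes the neighbourhood structure the
embedding should preserve, and it is already symmetric and stochastic.
The identity kernel (β = 0) has no off-diagonal mass and is rejected as
degenerate.

The layout fixes x at the trophic levels and moves y only, following the
standard Student-t t-SNE gradient restricted to the y component, with
momentum 0.5 → 0.8 (switch at iteration 250), early exaggeration ×4 for
100 iterations, adaptive per-coordinate gains, and y initialised from
N(0, 1e−4²) with a mandatory seed. The default learning rate is
scale-aware, `max(1, n / exaggeration)`: with globally normalised
affinities the gradient magnitude shrinks roughly as 1/n², and the large
constant steps customary in perplexity-based t-SNE oscillate on
small webs (measured: constant rates of 50–200 end above the initial KL
on a 10-node web, while the scale-aware rate converges to the same
optimum from every seed). A constant rate remains available in
`LayoutConfig`. Convergence stops the descent when |ΔKL| < 1e−7, tested
only after the late-momentum phase begins — earlier the descent is still
launching from the near-zero initialisation and ΔKL is transiently tiny.

Two-node components are returned at their seeded initialisation: with a
single off-diagonal pair both similarity matrices are forced to 1/2, the
objective is constant in y, and any movement would be noise.

Disconnected graphs are embedded per component. The kernel of a
disconnected graph is block-diagonal, cross-component affinities vanish,
and joint embedding would place components arbitrarily relative to each
other; per-component embedding makes that explicit, while the shared
x-axis (metaweb-anchored levels) keeps components comparable.

## Layout quality and β selection

Layouts are scored by a Moran spatial autocorrelation of the embedded
coordinate: `I = (n/Σw) · Σ w_ij (y_i−ȳ)(y_j−ȳ) / Σ(y_i−ȳ)²` with
weights `w = A + Aᵀ`. Only y enters — x is pinned, so its
autocorrelation carries no information about the optimisation. `select_beta`
runs the embedding per grid value under one seed and returns the full
profile plus the argmax (ties to the smallest β); per-β failures are
recorded as missing rather than aborting the profile. The full profile is
always reported: on highly symmetric webs (the pyramid) the index cancels
to ≈0 at every β and the argmax is meaningless, and users are encouraged
to inspect several β values rather than trust a single optimum.

## Channel separation

Increasing β makes same-channel nodes more kernel-similar relative to
cross-channel ones. The canonical study system is a two-channel web: one
basal node feeding two disjoint chains that rejoin at one apex. Chains
have length 4 (10 nodes): separation between developed channels is the
phenomenon of interest, and a 1–2 node "channel" is not a distinct energy
path — at the largest β examined (1.0) diffusion already spans such a
web and the raw-kernel separation profile turns over.

Two facts are established and tested separately:

* **Kernel level (deterministic):** mean between-channel minus
  within-channel raw kernel similarity decreases monotonically over
  β ∈ {0.01, 0.1, 0.5, 1.0}.
* **Layout level (seeded, median of 5 seeds):** channels stay separated
  in y (mean between-channel |Δy| exceeds within-channel) at every β.

The layout-level statement is deliberately weaker than the kernel-level
one: the embedding matches the *normalised* affinities, and the global
normalisation (dividing by total off-diagonal kernel mass, which grows
with β) reverses the raw-kernel monotonicity — measured on both the
affinity matrix and optimised layouts. Persistent separation, not
monotone growth, is what the embedding guarantees.

## Group-TL-tsne

Stage 1 embeds the aggregated web at the chosen resolution (cost scales
with group count, not node count). Stage 2 places each group's members
with a seeded Fruchterman–Reingold layout of the group's internal
subgraph, translated so the member centroid equals the group's embedded
coordinate and rescaled so the farthest member sits at
`group_diameter/2` (diameter in layout coordinate units, default 1.0,
per-group overrides allowed). Any deterministic local spread satisfies
the contract; Fruchterman–Reingold was chosen as the standard seeded
force layout in the graph stack used here. Group x-coordinates carry the
aggregated level by default; `pin_trophic_levels=True` re-pins each
node's x to its own level after centring. No overlap removal is
performed between group clouds.

## Aggregation

Group abundance is the sum of member abundances; the group-level link
probability is the abundance-weighted mean of member link weights
(`π̃_ql = Σ π p p' / (Σp · Σp')`). Total abundance is conserved, the
identity partition is a no-op, and nested aggregation is associative in
the abundances. An aggregated edge exists iff π̃ > 0; aggregated graphs
may carry self-loops (within-group feeding), which cancel in the
symmetrised Laplacian and hence do not disturb trophic levels. Groups
with zero total abundance among present nodes are absent from the
aggregated local network. Aggregating a web without abundances (the
metaweb) uses uniform weights p = 1/n — the least-informative choice,
noted in logs.

## Metrics, diversity, dissimilarity

Mean shortest path is the mean of finite directed unweighted shortest
paths over ordered reachable pairs; unreachable pairs are excluded so
the metric stays defined on disconnected local webs, and a single-node
web reports a missing value.

Node diversity is the Hill number `(Σ p^q)^(1/(1−q))` (Shannon limit at
q = 1); link diversity applies the same to the normalised link-strength
distribution `π_kl p_k p_l`. Pairwise dissimilarity uses the
multiplicative Hill decomposition for two equally weighted networks:
`D_β = D_γ / D_α ∈ [1, 2]`, normalised as `ln D_β / ln 2` at q = 1 and
`(1 − D_β^{1−q}) / (1 − 2^{1−q})` otherwise (the q → 1 limit matches; at
q = 0 this is `D_β − 1`, a Sørensen-type turnover). Dissimilarities lie
in [0, 1], with 0 for identical and 1 for disjoint assemblages. The
triangle inequality is *not* guaranteed and not asserted. Metaweb rows
use uniform node weights. The viewpoint parameter q defaults to 1;
q = 0 counts, larger q emphasises dominant nodes/links.

## Synthetic study systems

* **Pyramid** (layers 4,3,2,1 by default): every node preys on every
  node of the layer below; levels equal layer indices exactly, which
  pins the trophic-level solver and gives the canonical layout test.
* **Two-branch web** (chains of 4): the minimal system with two
  energetic channels; used for the separation properties above.
* **Random metanetwork:** DAG at target connectance 0.15 (upper triangle
  of a random node order, resampled to weak connectivity), 5 local
  communities from a symmetric Dirichlet with 30% independent zero
  masking — moderately uneven, moderately incomplete sampling — and an
  optional nested trophic table whose groups are contiguous blocks of
  the DAG order. Block grouping mimics functional guilds, which are
  trophically coherent; a uniformly random grouping connects every group
  to every other in both directions, collapsing all aggregated trophic
  levels to zero and making group layouts degenerate.

These systems exercise the mathematics, not the ecology: they contain no
sampling error in the *edges*, no abundance measurement noise, and no
trait structure, so passing tests demonstrate correctness of the
computations and the claimed invariants, not that layouts of real webs
will be informative. The case-study descriptions in the acceptance suite
run only when the corresponding third-party datasets are supplied
locally.

## Problem sizes

Default test and acceptance runs use webs of 3–100 nodes, 50 random
solver instances up to 200 nodes, embeddings of ≤ 1000 iterations, and
5-seed medians for stochastic claims — sizes at which every check runs
in seconds while still exercising dense linear algebra, per-component
logic and multi-resolution aggregation.
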