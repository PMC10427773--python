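"""TL-tsne layout of a pyramid web, with Moran-index beta selection.

The x-axis is the trophic level; the y-axis is found by minimising the KL
divergence between diffusion-kernel similarities and a Student-t layout
similarity.  Larger beta diffuses further and gathers nodes that share
energy paths.
"""

import networkx as nx
import pandas as pd

import trophicnet as tn

mn = tn.build_metanet(tn.make_pyramid([4, 3, 2, 1]))
tn.compute_TL(mn)
tl = pd.Series(nx.get_node_attributes(mn.metaweb.graph, "TL"))

profile = tn.select_beta(mn.metaweb.graph, tl, [0.04, 0.1, 0.35], tn.LayoutConfig(seed=1))
print(profile.frame().to_string(index=False))
print(f"selected beta = {profile.selected_beta}")
# The Moran index scores how strongly adjacent nodes share a y position;
# the argmax beta gives the most coherent channel structure.  On this
# fully symmetric pyramid the index cancels to ~0 at every beta (layer
# mates sit symmetrically about the axis) and ties resolve to the
# smallest beta; on asymmetric webs the profile is informative.

layout = profile.layouts[profile.selected_beta]
print(layout.coords.round(3).to_string())
print(f"KL: {layout.kl_initial:.4f} -> {layout.kl_final:.4f} in {layout.n_iter} iterations")
# x equals the trophic level exactly; y spreads nodes within each level.
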