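"""Build a metanetwork and compute Laplacian trophic levels.

A 4-node chain metaweb (a -> b -> c -> d, energy flowing up) is combined
with two local communities; trophic levels solve L x = v with the minimum
pinned to 0, and disconnected local components anchor to the metaweb scale.
"""

import networkx as nx
import pandas as pd

import trophicnet as tn

metaweb = tn.Metaweb([("a", "b"), ("b", "c"), ("c", "d")])
abundances = tn.AbundanceTable(
    pd.DataFrame(
        [[0.4, 0.3, 0.3, 0.0],   # community without the apex consumer
         [0.4, 0.3, 0.0, 0.3]],  # community missing c: {a,b} and {d} disconnect
        index=["site1", "site2"],
        columns=["a", "b", "c", "d"],
    )
)

mn = tn.build_metanet(metaweb, abundances)
tn.compute_TL(mn)

print(tn.trophic_levels_frame(mn).to_string(index=False))
# The metaweb chain solves to levels 0,1,2,3.  In site2 the isolated node d
# keeps its metaweb level (3): local levels stay comparable across sites.
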