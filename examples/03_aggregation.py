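"""Aggregate a metanetwork to a coarser resolution via a trophic table.

Group abundances are sums; group-to-group link probabilities are
abundance-weighted means of the pairwise link weights, so aggregation
conserves total abundance and the identity partition is a no-op.
"""

import pandas as pd

import trophicnet as tn

metaweb = tn.Metaweb([("plant", "herbivore1"), ("plant", "herbivore2"),
                      ("herbivore1", "predator"), ("herbivore2", "predator")])
abundances = tn.AbundanceTable(
    pd.DataFrame([[0.5, 0.2, 0.2, 0.1]], index=["site"],
                 columns=["plant", "herbivore1", "herbivore2", "predator"])
)
table = tn.TrophicTable(
    pd.DataFrame(
        {"guild": ["producers", "grazers", "grazers", "carnivores"]},
        index=pd.Index(["plant", "herbivore1", "herbivore2", "predator"], name="species"),
    )
)

mn = tn.build_metanet(metaweb, abundances, table)
tn.append_agg_nets(mn)

agg = mn.get_network("site", "guild")
print("aggregated abundances:")
print(agg.abundances.round(3).to_string())
for u, v, d in agg.graph.edges(data=True):
    print(f"  {u} -> {v}: link probability {d['weight']:.3f}")
# The two herbivores pool into one 0.4-abundance guild; the guild-level
# link probability averages the species-level links weighted by abundance.
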