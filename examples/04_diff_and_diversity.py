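"""Compare two local networks: difference network, metrics, Hill indices.

The difference network lives on the metaweb scaffold and records signed
abundance changes; Hill-number diversity and pairwise dissimilarity
summarise composition on nodes and links.
"""

import pandas as pd

import trophicnet as tn

metaweb = tn.Metaweb([("a", "b"), ("b", "c")])
abundances = tn.AbundanceTable(
    pd.DataFrame([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]],
                 index=["before", "after"], columns=["a", "b", "c"])
)
mn = tn.build_metanet(metaweb, abundances)
tn.compute_TL(mn)

diff = tn.diff_networks(mn, "before", "after")
print(diff.node_table().to_string(index=False))
# a is lost (only-first, delta +0.5), c is gained (only-second, -0.5).

print(tn.compute_metrics(mn).round(3).to_string(index=False))
print(tn.compute_div(mn, q=1.0).round(3).to_string(index=False))
mats = tn.compute_dis(mn, q=1.0)
print("node dissimilarity:", round(mats["nodes"].loc["before", "after"], 4))
# Shannon-order (q=1) dissimilarity is 0 for identical communities and 1
# for disjoint ones; here the two sites share only node b.
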