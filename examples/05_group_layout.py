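"""Group-TL-tsne: lay out a 50-node web via its 5-group aggregation.

The constrained t-SNE runs only on the small aggregated web; members of
each group are then spread around the group's coordinate by a seeded
force-directed layout, keeping the costly stage proportional to the
group count rather than the node count.
"""

import trophicnet as tn

spec = tn.FixtureSpec(n_nodes=50, connectance=0.12, n_communities=2,
                      group_sizes=(5,), seed=21)
mn = tn.make_random_metanetwork(spec)
tn.append_agg_nets(mn)
tn.compute_TL(mn)

resolution = mn.trophic_table.coarser_resolutions[0]
cfg = tn.GroupLayoutConfig(tsne=tn.LayoutConfig(beta=0.1, seed=1),
                           group_diameter=0.8, seed=1)
layout = tn.group_tl_tsne(mn, "metaweb", resolution, cfg)

part = mn.trophic_table.partition(resolution)
for group in sorted(part.unique()):
    members = [n for n in layout.nodes if part[n] == group]
    centre = layout.coords.loc[members].mean()
    print(f"{group}: {len(members):2d} members around "
          f"(x={centre['x']:.2f}, y={centre['y']:.2f})")
# Each group's cloud is centred at the group's embedded coordinate and no
# member sits farther than group_diameter/2 from that centre.
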