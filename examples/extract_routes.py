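"""Enumerate every retrosynthesis route embedded in a reaction network.

Uses the packaged worked example: a 20-compound, 15-reaction network of
the kind distilled from a single process patent.  Root compounds (those
appearing only as products) head the routes; complete depth-first search
recovers every route down to purchasable starting materials.
"""

from routestrat import demo_network, enumerate_pathways, find_roots, level_frontiers

net = demo_network()
print(f"network: {len(net.compounds)} compounds, {len(net.reactions)} reactions")
print(f"root compounds (candidate targets): {sorted(find_roots(net), key=int)}")

routes = enumerate_pathways(net, max_depth=20)
print(f"\n{len(routes)} routes found by complete DFS:")
for i, p in enumerate(routes, 1):
    chain = " -> ".join("[" + ", ".join(level) + "]" for level in level_frontiers(p))
    print(f"  ({i}) depth {p.depth}: {chain}")

# Each listing reads target -> reactant frontier per step; e.g. route (1)
# decomposes compound 1 into 5, 6 and 10, then expands 5 via 14, and so on
# until only starting materials (19, 20, ...) remain.
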