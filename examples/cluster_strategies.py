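"""Cluster pathway embeddings into strategy groups.

Trains a small ranker, embeds routes for several targets (each with a
step-order-swapped near-twin and a detour-corrupted variant), clusters
with HDBSCAN and prints the per-cluster report with shared intermediates.
"""

from routestrat import (
    FixtureSpec,
    TreeLSTMConfig,
    TreeLSTMRanker,
    cluster_pathways,
    cluster_report,
    corrupt,
    gen_dataset,
)

groups = gen_dataset(FixtureSpec(
    n_groups=24, seed=2, kinds=("detour_pair", "reversed_protection"),
    alternatives_per_group=(5, 8),
))
cfg = TreeLSTMConfig(embed_hidden=(128,), embed_dim=64, hidden_dim=64,
                     scorer_hidden=(32,), epochs=5, seed=0)
model = TreeLSTMRanker(cfg).train(groups[:20])

# for each held-back target: the reference, a strategy-preserving twin and
# a detour-corrupted variant
pathways = []
for i, g in enumerate(groups[20:]):
    ref = g.reference
    pathways += [ref, corrupt(ref, "step_order_swap", seed=i),
                 corrupt(ref, "detour_pair", seed=i)]

embs = [model.encode_pathway(p) for p in pathways]
assignments = cluster_pathways(embs, min_cluster_size=2)
report = cluster_report(assignments, pathways)
print(report[["cluster_id", "size", "representative"]].to_string(index=False))

n_noise = sum(a.cluster_id == -1 for a in assignments)
print(f"\n{len(report)} clusters, {n_noise} noise points "
      f"out of {len(pathways)} pathways")
# References and their step-order twins share a strategy and should share
# a cluster; detour variants carry extra nonproductive steps and tend to
# separate.  Shared intermediates per cluster are in report.shared_compounds.
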