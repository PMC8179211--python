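"""Rank the same groups with the three heuristic baselines.

Depth sorting (with worst/best-case tie bracketing), complexity-flow
min-pooling over linear chains, and the hybrid descriptor FFNN — the
reference points the learned ranker is judged against.
"""

from routestrat import (
    FixtureSpec,
    baseline_train,
    depth_topk,
    gen_dataset,
    rank_group,
    topk_accuracy,
)

groups = gen_dataset(FixtureSpec(
    n_groups=30, seed=1, kinds=("detour_pair", "reversed_protection"),
    alternatives_per_group=(5, 10),
))
train, test = groups[:24], groups[24:]

worst, best = depth_topk(test, 1)
print(f"depth baseline     top-1: {worst:.2f} (worst case) / {best:.2f} (best case)")

for which in ("scscore", "hybrid"):
    model = baseline_train(train, which)
    ranked = [rank_group(g, model) for g in test]
    print(f"{which:<18} top-1: {topk_accuracy(ranked, 1):.2f}")

# Detour corruptions lengthen routes, so depth alone already separates
# part of the alternatives (its best case assumes ties resolve in the
# reference's favor); the complexity-flow and hybrid baselines add
# structural signal but remain far from a learned pathway encoder.
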