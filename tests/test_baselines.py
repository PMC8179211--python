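"""Depth, complexity-flow and hybrid-descriptor baselines."""

import itertools

import numpy as np
import pytest

from routestrat.baselines import (
    BaselineConfig,
    FFNNBaseline,
    baseline_train,
    chain_complexity_vector,
    complexity,
    depth_rank,
    depth_topk,
    hybrid_descriptors,
    linearize,
    structural_complexity,
)
from routestrat.chem import Reaction
from routestrat.network import Pathway, PathwayGroup, PathwayNode
from routestrat.synthetic import FixtureSpec, gen_dataset, gen_reference_pathway
from routestrat.treelstm import rank_group, topk_accuracy


def _chain(depth: int, tag: str = "X", label="reference", pid="p") -> Pathway:
    node = None
    for i in range(depth, 0, -1):
        rxn = Reaction((f"{tag}{i}",), f"{tag}{i-1}", source_id="S")
        node = PathwayNode(rxn, (node,) if node else ())
    return Pathway(f"{tag}0", node, label=label, pathway_id=pid)


def _depth_group(ref_depth: int, alt_depths: list[int]) -> PathwayGroup:
    ref = _chain(ref_depth, "R", "reference", "ref")
    # alternatives re-rooted on the same target id for group validity
    alts = []
    for j, d in enumerate(alt_depths):
        p = _chain(d, f"A{j}_", "alternative", f"a{j}")
        alts.append(Pathway("R0", Pathway("x", p.root).root, label="alternative",
                            pathway_id=f"a{j}"))
    # rebuild alt roots so their product matches the shared target
    fixed = []
    for j, (d, a) in enumerate(zip(alt_depths, alts)):
        node = a.root
        new_root = PathwayNode(
            Reaction(node.reaction.reactants, "R0", source_id="S"), node.children
        )
        fixed.append(Pathway("R0", new_root, label="alternative", pathway_id=f"a{j}"))
    return PathwayGroup("R0", ref, fixed, "g")


class TestDepthRank:
    def test_tie_bracketing_example(self):
        worst, best = depth_rank(_depth_group(4, [4, 5]))
        assert (worst, best) == (2, 1)

    def test_strictly_shallowest_reference(self):
        assert depth_rank(_depth_group(3, [4, 5, 6])) == (1, 1)

    def test_all_equal_depths(self):
        g = _depth_group(4, [4, 4, 4])
        assert depth_rank(g) == (4, 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_bracket_covers_exhaustive_tie_permutations(self, seed):
        rng = np.random.default_rng(seed)
        depths = rng.integers(3, 7, size=rng.integers(2, 6))
        g = _depth_group(int(rng.integers(3, 7)), [int(d) for d in depths])
        worst, best = depth_rank(g)
        ps = g.pathways()
        achieved = set()
        for perm in itertools.permutations(range(len(ps))):
            order = sorted(perm, key=lambda i: (ps[i].depth, perm.index(i)))
            achieved.add(order.index(0) + 1)
        assert min(achieved) == best and max(achieved) == worst
        assert achieved == set(range(best, worst + 1))

    def test_depth_topk(self):
        groups = [_depth_group(4, [4, 5]), _depth_group(5, [4, 4])]
        worst, best = depth_topk(groups, 1)
        assert (worst, best) == (0.0, 0.5)


class TestLinearize:
    def test_linear_pathway_single_chain(self):
        p = _chain(4)
        chains = linearize(p)
        assert len(chains) == 1 and len(chains[0].steps) == 4
        assert chains[0].steps[0].product == "X0"  # root-first ordering

    @pytest.mark.parametrize("seed", range(10))
    def test_chain_count_equals_leaf_count(self, seed):
        p = gen_reference_pathway(FixtureSpec(seed=seed), seed=seed)
        leaves = sum(1 for n in p.nodes() if not n.children)
        assert len(linearize(p)) == leaves

    def test_full_binary_tree_four_chains(self):
        leaf = lambda i: PathwayNode(Reaction((f"L{i}",), f"B{i}", source_id="S"))
        mid1 = PathwayNode(Reaction(("B0", "B1"), "M0", source_id="S"),
                           (leaf(0), leaf(1)))
        mid2 = PathwayNode(Reaction(("B2", "B3"), "M1", source_id="S"),
                           (leaf(2), leaf(3)))
        root = PathwayNode(Reaction(("M0", "M1"), "T", source_id="S"), (mid1, mid2))
        assert len(linearize(Pathway("T", root))) == 4


class TestComplexity:
    def test_methane_pins_scale_floor(self):
        assert structural_complexity("C") == 1.0

    def test_ring_monotonicity(self):
        assert structural_complexity("C1CCCCC1") >= structural_complexity("CCCCCC")

    def test_hand_computed_table(self):
        # 1 + 0.06*(heavy-1) + 0.3*rings + 0.4*stereocenters, capped at 5
        table = {
            "C": 1.0,
            "CCO": 1.12,
            "c1ccccc1": 1.6,
            "CC(N)C(=O)O": 1.7,
            "BrCc1ccccc1": 1.72,
        }
        for smi, expect in table.items():
            assert structural_complexity(smi) == pytest.approx(expect)

    def test_pluggable_function(self):
        assert complexity("whatever", fn=lambda s: 3.5) == 3.5

    def test_unparseable_rejected(self):
        with pytest.raises(ValueError):
            structural_complexity("C1CC")


class TestChainVector:
    def test_padding_and_most_complex_reactant(self):
        steps = (
            Reaction.from_smiles(["c1ccccc1C(=O)O", "CCO"], "CCOC(=O)c1ccccc1"),
            Reaction.from_smiles(["c1ccccc1"], "c1ccccc1C(=O)O"),
        )
        from routestrat.baselines import LinearPathway

        vec = chain_complexity_vector(LinearPathway(steps), max_depth=5)
        assert vec.shape == (5,)
        assert vec[0] == structural_complexity("c1ccccc1C(=O)O")  # max of reactants
        assert vec[1] == structural_complexity("c1ccccc1")
        assert not vec[2:].any()


class TestHybridDescriptors:
    def test_single_node_pathway(self):
        p = Pathway("T", PathwayNode(Reaction(("B", "C"), "T")), pathway_id="s")
        d = hybrid_descriptors(p, fn=lambda s: float(len(s)))
        assert d.depth == 1 and d.n_nodes == 1 and d.n_leaves == 1
        assert d.n_linear_pathways == 1 and d.max_children == 0
        assert d.min_intermediate_complexity == 0.0
        assert d.max_intermediate_complexity == 0.0

    def test_demo_route_hand_counts(self):
        from routestrat.network import demo_network, enumerate_pathways

        p = next(p for p in enumerate_pathways(demo_network()) if p.target == "1")
        d = hybrid_descriptors(p, fn=lambda s: float(s))
        # route 1: five reactions, two leaf nodes (both from {19, 20})
        assert d.depth == 4 and d.n_nodes == 5 and d.n_leaves == 2
        assert d.n_linear_pathways == 2 and d.max_children == 2
        assert d.target_complexity == 1.0
        assert d.max_leaf_complexity == 20.0  # starting materials 6,10,16..20

    @pytest.mark.parametrize("seed", range(5))
    def test_delta_ordering_invariant(self, seed):
        p = gen_reference_pathway(FixtureSpec(seed=seed), seed=seed)
        d = hybrid_descriptors(p)
        assert d.min_step_delta <= d.max_step_delta
        assert d.n_leaves <= d.n_nodes


class TestFFNNBaselines:
    def test_singleton_min_pool(self):
        cfg = BaselineConfig(which="scscore", seed=1)
        model = FFNNBaseline(cfg, complexity_fn=lambda s: float(len(s)))
        p = _chain(3)
        x = (model.input_rows(p) - model.mu) / model.sd
        out, _ = model.mlp.forward(model.params, x)
        assert model.score_pathway(
            Pathway(p.target, p.root, pathway_id="x")
        ).slscore == pytest.approx(float(out.min()))

    @pytest.mark.parametrize("seed", range(6))
    def test_min_pool_dominance(self, seed):
        """Dropping the argmin chain never lowers the pathway score."""
        p = gen_reference_pathway(FixtureSpec(seed=seed), seed=seed)
        model = FFNNBaseline(BaselineConfig(which="scscore", seed=seed))
        x = (model.input_rows(p) - model.mu) / model.sd
        out, _ = model.mlp.forward(model.params, x)
        scores = out[:, 0]
        if len(scores) > 1:
            without_min = np.delete(scores, np.argmin(scores))
            assert without_min.min() >= scores.min()

    def test_two_chain_composition_oracle(self):
        model = FFNNBaseline(BaselineConfig(which="scscore", seed=3))
        leaf = lambda i, s: PathwayNode(Reaction.from_smiles([s], f"CC{'C'*i}O"))
        root = PathwayNode(
            Reaction.from_smiles(["CCO", "CCCO"], "CCOC(=O)CC"),
            (leaf(0, "CCBr"), leaf(1, "CCC=O")),
        )
        p = Pathway("CCOC(=O)CC", root, pathway_id="t")
        from routestrat.baselines import linearize

        chains = linearize(p)
        outs = []
        for c in chains:
            x = (chain_complexity_vector(c, None, model.cfg.max_depth) - model.mu) / model.sd
            out, _ = model.mlp.forward(model.params, x[None, :])
            outs.append(float(out[0, 0]))
        assert model.score_pathway(p).slscore == pytest.approx(min(outs))

    @pytest.mark.parametrize("which", ["scscore", "hybrid"])
    def test_trainable_above_chance(self, which, small_groups):
        cfg = BaselineConfig(which=which, seed=0, epochs=60)
        model = baseline_train(small_groups, which, cfg)
        ranked = [rank_group(g, model) for g in small_groups]
        top1 = topk_accuracy(ranked, 1)
        chance = np.mean([1 / len(g.pathways()) for g in small_groups])
        assert top1 > chance

    def test_seed_determinism(self, small_groups):
        a = baseline_train(small_groups[:4], "hybrid",
                           BaselineConfig(which="hybrid", seed=5, epochs=5))
        b = baseline_train(small_groups[:4], "hybrid",
                           BaselineConfig(which="hybrid", seed=5, epochs=5))
        assert a.history == b.history

    def test_zero_epochs_leave_params_unchanged(self, small_groups):
        cfg = BaselineConfig(which="hybrid", seed=2, epochs=0)
        fresh = FFNNBaseline(cfg)
        before = {k: v.copy() for k, v in fresh.params.items()}
        fresh.train(small_groups[:3])
        assert all(np.array_equal(before[k], fresh.params[k]) for k in before)
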