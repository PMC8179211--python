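"""Tree-LSTM encoder, SLScore ranking, group-wise training contracts."""

import numpy as np
import pytest

from routestrat.chem import Reaction, featurize
from routestrat.network import Pathway, PathwayGroup, PathwayNode
from routestrat.nn import sigmoid
from routestrat.synthetic import FixtureSpec, gen_dataset, gen_reference_pathway
from routestrat.treelstm import (
    RankedGroup,
    ScoredPathway,
    TreeLSTMConfig,
    TreeLSTMRanker,
    rank_group,
    split_by_source,
    topk_accuracy,
)

from conftest import linear_pathway, tiny_cfg


def chain_lstm_oracle(model: TreeLSTMRanker, features: list[np.ndarray]) -> np.ndarray:
    """Plain sequential LSTM sharing the model's weights, run leaf-to-root."""
    P = model.params
    h_dim = model.cfg.hidden_dim
    h = np.zeros(h_dim)
    c = np.zeros(h_dim)
    first = True
    for e in features:  # leaf first, already embedded
        z = e @ P["lstm.Wx"] + P["lstm.b"] + h @ P["lstm.U"]
        i = sigmoid(z[:h_dim])
        o = sigmoid(z[h_dim : 2 * h_dim])
        u = np.tanh(z[2 * h_dim :])
        if first:
            c = i * u
            first = False
        else:
            f = sigmoid(e @ P["lstm.Wxf"] + P["lstm.bf"] + h @ P["lstm.Uf"])
            c = i * u + f * c
        h = o * np.tanh(c)
    return h


def embedded_inputs(model: TreeLSTMRanker, p: Pathway) -> list[np.ndarray]:
    """Reaction embeddings of an unbranched pathway, leaf first."""
    order = []
    node = p.root
    while True:
        order.append(node)
        if not node.children:
            break
        (node,) = node.children
    return [model.embed_node(featurize(n.reaction)) for n in reversed(order)]


class TestEmbedNode:
    def test_zero_weights_give_zero_output(self, tiny_model):
        for key, arr in tiny_model.params.items():
            if key.startswith("emb."):
                arr[:] = 0.0
        feat = featurize(Reaction.from_smiles(["CCO"], "CC=O"))
        assert not tiny_model.embed_node(feat).any()

    def test_seed_determinism(self):
        feat = featurize(Reaction.from_smiles(["CCO"], "CC=O"))
        a = TreeLSTMRanker(tiny_cfg()).embed_node(feat)
        b = TreeLSTMRanker(tiny_cfg()).embed_node(feat)
        assert np.array_equal(a, b)

    def test_matches_explicit_matrix_oracle(self, tiny_model):
        feat = featurize(Reaction.from_smiles(["CCCO"], "CCC=O"))
        x = feat.concat().astype(float)
        P = tiny_model.params
        oracle = np.maximum(x @ P["emb.W0"] + P["emb.b0"], 0) @ P["emb.W1"] + P["emb.b1"]
        assert np.abs(tiny_model.embed_node(feat) - oracle).max() < 1e-6

    def test_dimension_mismatch_rejected(self, tiny_model):
        from routestrat.chem import NodeFeatures

        bad = NodeFeatures(np.zeros(16, dtype=np.uint8), np.zeros(16, dtype=np.int32))
        with pytest.raises(ValueError):
            tiny_model.embed_node(bad)


class TestEncodePathway:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_child_permutation_invariance(self, tiny_model, seed):
        p = gen_reference_pathway(FixtureSpec(seed=seed), seed=seed)

        def flip(node: PathwayNode) -> PathwayNode:
            return PathwayNode(node.reaction,
                               tuple(flip(c) for c in reversed(node.children)))

        flipped = Pathway(p.target, flip(p.root), pathway_id=p.pathway_id)
        a = tiny_model.encode_pathway(p).vector
        b = tiny_model.encode_pathway(flipped).vector
        assert np.abs(a - b).max() <= 1e-6

    def test_linear_pathway_equals_chain_lstm(self, tiny_model):
        p = linear_pathway(["CC(=O)O", "CCO", "CCBr", "CC"])
        got = tiny_model.encode_pathway(p).vector
        oracle = chain_lstm_oracle(tiny_model, embedded_inputs(tiny_model, p))
        assert np.abs(got - oracle).max() <= 1e-6

    def test_single_node_equals_one_lstm_cell(self, tiny_model):
        rxn = Reaction.from_smiles(["CCO"], "CC=O")
        p = Pathway("CC=O", PathwayNode(rxn), pathway_id="single")
        oracle = chain_lstm_oracle(
            tiny_model, [tiny_model.embed_node(featurize(rxn))]
        )
        assert np.abs(tiny_model.encode_pathway(p).vector - oracle).max() <= 1e-6


class TestScorePathway:
    def test_zero_scorer_scores_zero(self, tiny_model):
        for key, arr in tiny_model.params.items():
            if key.startswith("scorer."):
                arr[:] = 0.0
        p = linear_pathway(["CC(=O)O", "CCO"])
        assert tiny_model.score_pathway(p).slscore == 0.0

    def test_bit_stable_and_composes(self, tiny_model):
        p = linear_pathway(["CC(=O)O", "CCO", "CC"])
        s1 = tiny_model.score_pathway(p).slscore
        s2 = tiny_model.score_pathway(p).slscore
        assert s1 == s2
        emb = tiny_model.encode_pathway(p).vector
        oracle, _ = tiny_model.scorer.forward(tiny_model.params, emb[None, :])
        assert abs(s1 - float(oracle[0, 0])) < 1e-9


class _StubModel:
    def __init__(self, scores):
        self.scores = scores

    def score_pathway(self, p):
        return ScoredPathway(p.pathway_id, self.scores[p.pathway_id])


def _stub_group(ids):
    mk = lambda pid, label: Pathway(
        "T", PathwayNode(Reaction(("B",), "T")), pathway_id=pid, label=label
    )
    return PathwayGroup("T", mk(ids[0], "reference"),
                        [mk(i, "alternative") for i in ids[1:]], group_id="g")


class TestRankGroup:
    def test_highest_score_first(self):
        g = _stub_group(["ref", "a1", "a2"])
        rg = rank_group(g, _StubModel({"ref": 2.0, "a1": 1.0, "a2": 0.5}))
        assert [s.pathway_id for s in rg.ranking] == ["ref", "a1", "a2"]
        assert rg.reference_rank == 1

    def test_ties_break_by_pathway_id(self):
        g = _stub_group(["ref", "a1", "a2"])
        rg = rank_group(g, _StubModel({"ref": 1.0, "a1": 1.0, "a2": 1.0}))
        assert [s.pathway_id for s in rg.ranking] == ["a1", "a2", "ref"]

    def test_invariant_under_monotone_transform(self):
        g = _stub_group(["ref", "a1", "a2", "a3"])
        raw = {"ref": 0.3, "a1": -1.0, "a2": 2.0, "a3": 0.0}
        base = rank_group(g, _StubModel(raw))
        warped = rank_group(g, _StubModel({k: np.tanh(3 * v) + 7 for k, v in raw.items()}))
        assert [s.pathway_id for s in base.ranking] == [
            s.pathway_id for s in warped.ranking
        ]


class TestTopK:
    def test_counts_reference_positions(self):
        rgs = [
            RankedGroup(f"g{i}", "ref",
                        [ScoredPathway("x", 0.0)] * (r - 1)
                        + [ScoredPathway("ref", 0.0)]
                        + [ScoredPathway("y", 0.0)] * 5)
            for i, r in enumerate([1, 3, 6, 2])
        ]
        assert topk_accuracy(rgs, 5) == 0.75
        assert topk_accuracy(rgs, 1) == 0.25
        assert topk_accuracy(rgs, 100) == 1.0

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            topk_accuracy([], 0)


class TestTrain:
    def test_separable_toy_reference_wins(self, small_groups):
        g = small_groups[0]
        toy = PathwayGroup(g.target, g.reference, g.alternatives[:1], "toy")
        cfg = tiny_cfg(epochs=200, batch_groups=1, learning_rate=3e-3)
        model = TreeLSTMRanker(cfg).train([toy])
        _, scores = model.group_loss(toy.pathways())
        probs = np.exp(scores) / np.exp(scores).sum()
        assert probs[0] > 0.5

    def test_seed_reproducibility(self, small_groups):
        cfg = tiny_cfg(epochs=3)
        a = TreeLSTMRanker(cfg).train(small_groups[:4])
        b = TreeLSTMRanker(tiny_cfg(epochs=3)).train(small_groups[:4])
        assert a.history == b.history

    def test_loss_decreases_on_average(self, small_groups):
        model = TreeLSTMRanker(tiny_cfg(epochs=6)).train(small_groups)
        assert np.mean(model.history[-2:]) < np.mean(model.history[:2])

    def test_empty_and_degenerate_groups_rejected(self, small_groups):
        with pytest.raises(ValueError):
            TreeLSTMRanker(tiny_cfg()).train([])
        g = small_groups[0]
        bad = PathwayGroup(g.target, g.reference, [], "empty")
        with pytest.raises(ValueError):
            TreeLSTMRanker(tiny_cfg()).train([bad])

    def test_gradient_matches_finite_differences(self, small_groups):
        """Autodiff-by-hand agrees with central differences on a 2-pathway group."""
        model = TreeLSTMRanker(tiny_cfg())
        group = small_groups[0].pathways()[:2]
        grads = {}
        model.group_loss(group, grads)
        rng = np.random.default_rng(7)
        eps = 1e-6
        for key in sorted(grads):
            arr = model.params[key]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                old = arr[idx]
                arr[idx] = old + eps
                lp, _ = model.group_loss(group)
                arr[idx] = old - eps
                lm, _ = model.group_loss(group)
                arr[idx] = old
                fd = (lp - lm) / (2 * eps)
                an = np.asarray(grads[key])[idx]
                assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd), abs(an))

    def test_pairwise_loss_variant_trains(self, small_groups):
        cfg = tiny_cfg(epochs=3, loss="pairwise")
        model = TreeLSTMRanker(cfg).train(small_groups[:4])
        assert len(model.history) == 3 and np.isfinite(model.history).all()


class TestCheckpoint:
    def test_round_trip(self, tmp_path, small_groups):
        model = TreeLSTMRanker(tiny_cfg(epochs=1)).train(small_groups[:3])
        path = tmp_path / "model.ckpt.npz"
        model.save(path)
        again = TreeLSTMRanker.load(path)
        p = small_groups[0].reference
        assert model.score_pathway(p).slscore == again.score_pathway(p).slscore

    def test_fp_dim_mismatch_refused(self, tmp_path):
        model = TreeLSTMRanker(tiny_cfg())
        model.cfg.fp_dim = 1024
        path = tmp_path / "bad.ckpt.npz"
        model.save(path)
        with pytest.raises(ValueError, match="fp_dim"):
            TreeLSTMRanker.load(path)


class TestSplitBySource:
    def _groups(self, n_sources, per_source=2):
        out = []
        for s in range(n_sources):
            for j in range(per_source):
                p = Pathway("T", PathwayNode(Reaction(("B",), "T")),
                            source_id=f"S{s}", pathway_id=f"S{s}/{j}")
                alt = Pathway("T", PathwayNode(Reaction(("C",), "T")),
                              source_id=f"S{s}", label="alternative")
                out.append(PathwayGroup("T", p, [alt], f"S{s}-g{j}"))
        return out

    def test_ten_sources_split_8_1_1(self):
        tr, va, te = split_by_source(self._groups(10), seed=4)
        srcs = lambda gs: {g.source_id for g in gs}
        assert len(srcs(tr)) == 8 and len(srcs(va)) == 1 and len(srcs(te)) == 1

    def test_same_seed_same_partition(self):
        gs = self._groups(7)
        a = split_by_source(gs, seed=9)
        b = split_by_source(gs, seed=9)
        assert all([g.group_id for g in x] == [g.group_id for g in y]
                   for x, y in zip(a, b))

    def test_no_source_in_two_splits(self):
        for seed in range(5):
            tr, va, te = split_by_source(self._groups(9), seed=seed)
            s = [{g.source_id for g in part} for part in (tr, va, te)]
            assert not (s[0] & s[1]) and not (s[0] & s[2]) and not (s[1] & s[2])
            assert s[0] | s[1] | s[2] == {f"S{i}" for i in range(9)}

    def test_too_few_sources_rejected(self):
        with pytest.raises(ValueError, match="sources"):
            split_by_source(self._groups(2))
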