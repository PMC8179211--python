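"""Dynamic child-sum tree-LSTM pathway encoder and strategy-level ranker.

Every reaction node of a pathway tree is featurized (product fingerprint +
difference reaction fingerprint), embedded by a feed-forward network, and
fed to an LSTM cell whose structure mirrors the pathway tree: evaluation
runs from the leaves towards the root, children aggregated by a direct sum
of hidden states and a weighted sum of cell states gated by one forget
gate per child.  The root hidden state is the pathway embedding; a scorer
network maps it to the scalar strategy-level score (SLScore), which is
meaningful only relative to other pathways sharing the same target.

Training is group-wise: each group holds one reference pathway (the route
actually practiced) and several machine-generated alternatives, and the
listwise softmax cross-entropy pushes the reference's score above the
alternatives'.  All arithmetic is numpy with hand-written backprop, so
runs are bit-reproducible given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .chem import FP_BITS, NodeFeatures, featurize
from .network import Pathway, PathwayGroup
from .nn import DTYPE, MLP, Adam, accumulate, glorot, sigmoid, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "TreeLSTMConfig",
    "TreeLSTMRanker",
    "PathwayEmbedding",
    "ScoredPathway",
    "RankedGroup",
    "encode_pathway",
    "score_pathway",
    "rank_group",
    "topk_accuracy",
    "split_by_source",
]


@dataclass
class TreeLSTMConfig:
    """Model and training hyperparameters (all exposed, seeds everything)."""

    fp_dim: int = FP_BITS
    embed_hidden: tuple[int, ...] = (512,)
    embed_dim: int = 256
    hidden_dim: int = 256
    scorer_hidden: tuple[int, ...] = (128,)
    seed: int = 0
    learning_rate: float = 1e-3
    epochs: int = 8
    batch_groups: int = 8
    max_alternatives: int = 300
    loss: str = "listwise"  # or "pairwise"

    def __post_init__(self) -> None:
        self.embed_hidden = tuple(self.embed_hidden)
        self.scorer_hidden = tuple(self.scorer_hidden)
        for name in ("fp_dim", "embed_dim", "hidden_dim", "epochs", "batch_groups"):
            if getattr(self, name) < (0 if name == "epochs" else 1):
                raise ValueError(f"{name} must be positive")
        if self.loss not in ("listwise", "pairwise"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass(frozen=True)
class PathwayEmbedding:
    vector: np.ndarray  # root hidden state, length hidden_dim
    pathway_id: str


@dataclass(frozen=True)
class ScoredPathway:
    pathway_id: str
    slscore: float


@dataclass
class RankedGroup:
    group_id: str
    reference_id: str
    ranking: list[ScoredPathway]

    @property
    def reference_rank(self) -> int:
        for pos, s in enumerate(self.ranking, 1):
            if s.pathway_id == self.reference_id:
                return pos
        raise ValueError(f"reference {self.reference_id!r} missing from ranking")


class _PathwayCache:
    """Static per-pathway tensors: post-order nodes + sparse features."""

    __slots__ = ("children", "features", "n")

    def __init__(self, p: Pathway):
        post: list = []

        def visit(node) -> int:
            kids = [visit(c) for c in node.children]
            post.append((node, kids))
            return len(post) - 1

        visit(p.root)
        self.n = len(post)
        self.children = [kids for _, kids in post]
        rows, cols, vals = [], [], []
        for j, (node, _) in enumerate(post):
            feat = featurize(node.reaction)
            x = feat.concat()
            nz = np.nonzero(x)[0]
            rows.extend([j] * len(nz))
            cols.extend(nz.tolist())
            vals.extend(x[nz].tolist())
        self.features = sp.csr_matrix(
            (np.asarray(vals, dtype=DTYPE), (rows, cols)),
            shape=(self.n, 2 * FP_BITS),
        )


class TreeLSTMRanker:
    """Child-sum tree-LSTM encoder + FFNN scorer with manual backprop."""

    def __init__(self, cfg: Optional[TreeLSTMConfig] = None,
                 params: Optional[dict] = None):
        self.cfg = cfg or TreeLSTMConfig()
        c = self.cfg
        self.emb = MLP("emb", (2 * c.fp_dim, *c.embed_hidden, c.embed_dim))
        self.scorer = MLP("scorer", (c.hidden_dim, *c.scorer_hidden, 1))
        self.params = params if params is not None else self._init_params()
        # keyed by object identity to avoid re-hashing deep trees; the
        # pathway itself is kept alive alongside its cache
        self._cache: dict[int, tuple[Pathway, _PathwayCache]] = {}

    # -- parameters ---------------------------------------------------------

    def _init_params(self) -> dict:
        c = self.cfg
        rng = np.random.default_rng(c.seed)
        params: dict = {}
        self.emb.init(params, rng)
        self.scorer.init(params, rng)
        e, h = c.embed_dim, c.hidden_dim
        params["lstm.Wx"] = glorot(rng, e, 3 * h)  # gates i, o, u on the input
        params["lstm.Wxf"] = glorot(rng, e, h)  # forget-gate input map
        params["lstm.U"] = glorot(rng, h, 3 * h)  # gates i, o, u on sum(h_child)
        params["lstm.Uf"] = glorot(rng, h, h)  # per-child forget gate on h_child
        params["lstm.b"] = np.zeros(3 * h, dtype=DTYPE)
        params["lstm.bf"] = np.ones(h, dtype=DTYPE)  # forget bias +1
        return params

    # -- forward ------------------------------------------------------------

    def _prepared(self, p: Pathway) -> _PathwayCache:
        entry = self._cache.get(id(p))
        if entry is None or entry[0] is not p:
            entry = self._cache[id(p)] = (p, _PathwayCache(p))
        return entry[1]

    def embed_node(self, feat: NodeFeatures) -> np.ndarray:
        """Reaction embedding: the FFNN on the concatenated fingerprints."""
        x = feat.concat().astype(DTYPE)
        if x.shape[0] != 2 * self.cfg.fp_dim:
            raise ValueError(
                f"feature length {x.shape[0]} != 2*fp_dim {2 * self.cfg.fp_dim}"
            )
        out, _ = self.emb.forward(self.params, x[None, :])
        return out[0]

    def _forward_trees(self, pathways: Sequence[Pathway]) -> tuple[list[dict], list]:
        """Batched embedding pass + per-pathway tree-LSTM passes."""
        preps = [self._prepared(p) for p in pathways]
        X = sp.vstack([prep.features for prep in preps], format="csr")
        E_all, emb_cache = self.emb.forward(self.params, X)
        fwds = []
        offset = 0
        for p, prep in zip(pathways, preps):
            E = E_all[offset : offset + prep.n]
            offset += prep.n
            fwds.append(self._forward_tree(p, prep, E))
        return fwds, emb_cache

    def _forward_tree(self, p: Pathway, prep: _PathwayCache, E: np.ndarray) -> dict:
        """Post-order tree-LSTM pass; returns all per-node activations."""
        c = self.cfg
        P = self.params
        h_dim = c.hidden_dim
        Ziou = E @ P["lstm.Wx"] + P["lstm.b"]
        Zf_x = E @ P["lstm.Wxf"] + P["lstm.bf"]
        H = np.zeros((prep.n, h_dim), dtype=DTYPE)
        C = np.zeros((prep.n, h_dim), dtype=DTYPE)
        Htilde = np.zeros((prep.n, h_dim), dtype=DTYPE)
        gates = []
        for j, kids in enumerate(prep.children):
            h_tilde = H[kids].sum(axis=0) if kids else np.zeros(h_dim, dtype=DTYPE)
            Htilde[j] = h_tilde
            z = Ziou[j] + h_tilde @ P["lstm.U"]
            i = sigmoid(z[:h_dim])
            o = sigmoid(z[h_dim : 2 * h_dim])
            u = np.tanh(z[2 * h_dim :])
            cell = i * u
            fks = []
            for k in kids:
                f = sigmoid(Zf_x[j] + H[k] @ P["lstm.Uf"])
                fks.append(f)
                cell = cell + f * C[k]
            H[j] = o * np.tanh(cell)
            C[j] = cell
            gates.append((i, o, u, fks))
            if not np.all(np.isfinite(H[j])):
                raise FloatingPointError(
                    f"non-finite state at node {j} of pathway {p.pathway_id!r}"
                )
        return {
            "prep": prep, "E": E, "H": H, "C": C,
            "Htilde": Htilde, "gates": gates,
        }

    def encode_pathway(self, p: Pathway) -> PathwayEmbedding:
        """Root hidden state of the tree-LSTM: the pathway's latent vector."""
        fwds, _ = self._forward_trees([p])
        return PathwayEmbedding(vector=fwds[0]["H"][-1].copy(),
                                pathway_id=p.pathway_id)

    def score_pathway(self, p: Pathway) -> ScoredPathway:
        """SLScore: the scorer FFNN applied to the pathway embedding."""
        fwds, _ = self._forward_trees([p])
        s, _ = self.scorer.forward(self.params, fwds[0]["H"][-1][None, :])
        return ScoredPathway(pathway_id=p.pathway_id, slscore=float(s[0, 0]))

    # -- backward -----------------------------------------------------------

    def _backward_tree(self, fwd: dict, d_root_h: np.ndarray, grads: dict
                       ) -> np.ndarray:
        P = self.params
        h_dim = self.cfg.hidden_dim
        prep, E, H, C, Htilde, gates = (
            fwd["prep"], fwd["E"], fwd["H"], fwd["C"], fwd["Htilde"], fwd["gates"],
        )
        n = prep.n
        dH = np.zeros_like(H)
        dC = np.zeros_like(C)
        dH[n - 1] = d_root_h
        dE = np.zeros_like(E)
        dZiou = np.zeros((n, 3 * h_dim), dtype=DTYPE)
        f_rows_h, f_rows_dz, f_rows_j = [], [], []
        for j in range(n - 1, -1, -1):
            i, o, u, fks = gates[j]
            kids = prep.children[j]
            tc = np.tanh(C[j])
            dh = dH[j]
            dzo = dh * tc * o * (1.0 - o)
            dc = dC[j] + dh * o * (1.0 - tc * tc)
            dzi = dc * u * i * (1.0 - i)
            dzu = dc * i * (1.0 - u * u)
            dz = np.concatenate([dzi, dzo, dzu])
            dZiou[j] = dz
            dh_tilde = dz @ P["lstm.U"].T
            dzf_sum = np.zeros(h_dim, dtype=DTYPE)
            for k, f in zip(kids, fks):
                df = dc * C[k]
                dzf = df * f * (1.0 - f)
                dzf_sum += dzf
                dC[k] += dc * f
                dH[k] += dzf @ P["lstm.Uf"].T + dh_tilde
                f_rows_h.append(H[k])
                f_rows_dz.append(dzf)
                f_rows_j.append(j)
            dE[j] = dz @ P["lstm.Wx"].T
            if kids:
                dE[j] += dzf_sum @ P["lstm.Wxf"].T
        accumulate(grads, "lstm.Wx", E.T @ dZiou)
        accumulate(grads, "lstm.U", Htilde.T @ dZiou)
        accumulate(grads, "lstm.b", dZiou.sum(axis=0))
        if f_rows_h:
            Hk = np.stack(f_rows_h)
            dZf = np.stack(f_rows_dz)
            Ej = E[f_rows_j]
            accumulate(grads, "lstm.Uf", Hk.T @ dZf)
            accumulate(grads, "lstm.Wxf", Ej.T @ dZf)
            accumulate(grads, "lstm.bf", dZf.sum(axis=0))
        return dE

    def group_loss(self, group: Sequence[Pathway], grads: Optional[dict] = None
                   ) -> tuple[float, np.ndarray]:
        """Loss of one group; ``group[0]`` is the reference pathway.

        Returns (loss, scores).  When ``grads`` is given, backpropagates.
        """
        fwds, emb_cache = self._forward_trees(group)
        roots = np.stack([f["H"][-1] for f in fwds])
        s, scorer_cache = self.scorer.forward(self.params, roots)
        scores = s[:, 0]
        if self.cfg.loss == "listwise":
            probs = softmax(scores)
            loss = -float(np.log(max(probs[0], 1e-300)))
            ds = probs.copy()
            ds[0] -= 1.0
        else:  # pairwise logistic against the reference
            margins = scores[1:] - scores[0]
            loss = float(np.sum(np.logaddexp(0.0, margins)))
            sig = sigmoid(margins)
            ds = np.concatenate([[-sig.sum()], sig])
        if grads is not None:
            d_roots = self.scorer.backward(
                self.params, grads, scorer_cache, ds[:, None]
            )
            dE_blocks = [
                self._backward_tree(f, d, grads) for f, d in zip(fwds, d_roots)
            ]
            self.emb.backward(self.params, grads, emb_cache, np.vstack(dE_blocks))
        return loss, scores

    # -- training -----------------------------------------------------------

    def train(self, groups: Sequence[PathwayGroup],
              val_groups: Sequence[PathwayGroup] = ()) -> "TreeLSTMRanker":
        """Group-wise ranking training; reproducible from ``cfg.seed``."""
        if not groups:
            raise ValueError("no training groups")
        for g in groups:
            if not g.alternatives:
                raise ValueError(f"group {g.group_id!r} has no alternatives")
        c = self.cfg
        rng = np.random.default_rng(c.seed + 1)
        batches = [
            [g.reference, *(
                g.alternatives
                if len(g.alternatives) <= c.max_alternatives
                else [g.alternatives[i] for i in sorted(rng.choice(
                    len(g.alternatives), c.max_alternatives, replace=False))]
            )]
            for g in groups
        ]
        opt = Adam(lr=c.learning_rate)
        self.history: list[float] = []
        for epoch in range(c.epochs):
            order = rng.permutation(len(batches))
            total = 0.0
            for start in range(0, len(order), c.batch_groups):
                idx = order[start : start + c.batch_groups]
                grads: dict = {}
                for gi in idx:
                    loss, _ = self.group_loss(batches[gi], grads)
                    total += loss
                for key in grads:
                    grads[key] = grads[key] / len(idx)
                opt.step(self.params, grads)
            mean_loss = total / len(batches)
            self.history.append(mean_loss)
            msg = f"epoch {epoch + 1}/{c.epochs} loss {mean_loss:.4f}"
            if val_groups:
                top1 = topk_accuracy([rank_group(g, self) for g in val_groups], 1)
                msg += f" val_top1 {top1:.3f}"
            logger.info(msg)
        return self

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint with embedded config."""
        cfg = asdict(self.cfg)
        np.savez(path, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "TreeLSTMRanker":
        with np.load(path) as archive:
            cfg_dict = json.loads(bytes(archive["__config__"]).decode())
            cfg_dict["embed_hidden"] = tuple(cfg_dict["embed_hidden"])
            cfg_dict["scorer_hidden"] = tuple(cfg_dict["scorer_hidden"])
            cfg = TreeLSTMConfig(**cfg_dict)
            if cfg.fp_dim != FP_BITS:
                raise ValueError(
                    f"checkpoint fp_dim {cfg.fp_dim} != expected {FP_BITS}"
                )
            params = {k: archive[k] for k in archive.files if k != "__config__"}
        return cls(cfg, params)


# ---------------------------------------------------------------------------
# Module-level operations


def encode_pathway(p: Pathway, model: TreeLSTMRanker) -> PathwayEmbedding:
    return model.encode_pathway(p)


def score_pathway(p: Pathway, model: TreeLSTMRanker) -> ScoredPathway:
    return model.score_pathway(p)


def rank_group(g: PathwayGroup, model: TreeLSTMRanker) -> RankedGroup:
    """Descending SLScore ranking; ties broken by pathway_id (deterministic)."""
    scored = [model.score_pathway(p) for p in g.pathways()]
    scored.sort(key=lambda s: (-s.slscore, s.pathway_id))
    return RankedGroup(
        group_id=g.group_id,
        reference_id=g.reference.pathway_id,
        ranking=scored,
    )


def topk_accuracy(ranked_groups: Sequence[RankedGroup], k: int) -> float:
    """Fraction of groups whose reference ranks within the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not ranked_groups:
        raise ValueError("no ranked groups")
    hits = sum(1 for rg in ranked_groups if rg.reference_rank <= k)
    return hits / len(ranked_groups)


def split_by_source(
    groups: Sequence[PathwayGroup],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[PathwayGroup], list[PathwayGroup], list[PathwayGroup]]:
    """Train/validation/test split that partitions *sources*, not groups.

    Every group of a given source lands wholly in one split, so no source
    (e.g. patent) contributes to two splits.  Proportions are within one
    source of the requested fractions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    sources = sorted({g.source_id for g in groups})
    if len(sources) < 3:
        raise ValueError("need at least 3 distinct sources to split")
    rng = np.random.default_rng(seed)
    order = [sources[i] for i in rng.permutation(len(sources))]
    n = len(order)
    n_train = round(fractions[0] * n)
    n_val = round(fractions[1] * n)
    n_val = max(1, min(n_val, n - n_train - 1))
    n_train = max(1, min(n_train, n - n_val - 1))
    buckets = (
        set(order[:n_train]),
        set(order[n_train : n_train + n_val]),
        set(order[n_train + n_val :]),
    )
    return tuple([g for g in groups if g.source_id in b] for b in buckets)  # type: ignore
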