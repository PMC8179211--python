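"""Shared fixtures: tiny model configs, random networks, and the two
session-scoped synthetic ranking experiments used by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from routestrat.chem import Reaction
from routestrat.network import Pathway, PathwayNode, build_network
from routestrat.synthetic import FixtureSpec, gen_dataset
from routestrat.treelstm import TreeLSTMConfig, TreeLSTMRanker


def tiny_cfg(**overrides) -> TreeLSTMConfig:
    base = dict(embed_hidden=(32,), embed_dim=16, hidden_dim=16,
                scorer_hidden=(8,), seed=0, epochs=2)
    base.update(overrides)
    return TreeLSTMConfig(**base)


@pytest.fixture
def tiny_model() -> TreeLSTMRanker:
    return TreeLSTMRanker(tiny_cfg())


@pytest.fixture(scope="session")
def small_groups():
    """A quick 8-group fixture for unit-level checks."""
    return gen_dataset(FixtureSpec(n_groups=8, seed=11,
                                   alternatives_per_group=(5, 8)))


def linear_pathway(smiles_chain: list[str], pathway_id: str = "lin") -> Pathway:
    """Unbranched pathway: each compound made from the next one down."""
    node = None
    for i in range(len(smiles_chain) - 1, 0, -1):
        rxn = Reaction.from_smiles([smiles_chain[i]], smiles_chain[i - 1])
        node = PathwayNode(rxn, (node,) if node else ())
    return Pathway(target=rxn.product, root=node, pathway_id=pathway_id)


def random_id_network(rng: np.random.Generator, max_reactions: int = 8):
    """Random small reaction network over opaque compound ids.

    May contain directed cycles and multiple producers per compound,
    exercising the cycle guard and the Cartesian expansion semantics.
    """
    n_compounds = int(rng.integers(4, 10))
    compounds = [f"M{i}" for i in range(n_compounds)]
    n_rxn = int(rng.integers(1, max_reactions + 1))
    reactions = []
    for _ in range(n_rxn):
        product = compounds[rng.integers(n_compounds)]
        k = int(rng.integers(1, 4))
        pool = [c for c in compounds if c != product]
        picks = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        reactions.append(
            Reaction(reactants=tuple(pool[i] for i in picks), product=product,
                     source_id="RAND")
        )
    return build_network(reactions, "RAND")


# ---------------------------------------------------------------------------
# Session-scoped synthetic ranking experiments (shared by end-to-end tests)

N_TRAIN, N_TEST = 200, 50


def _experiment(depth_matched: bool):
    spec = FixtureSpec(
        n_groups=N_TRAIN + N_TEST,
        seed=0,
        kinds=("detour_pair", "reversed_protection"),
        depth_matched=depth_matched,
    )
    groups = gen_dataset(spec)
    train, test = groups[:N_TRAIN], groups[N_TRAIN:]
    model = TreeLSTMRanker(TreeLSTMConfig(seed=0)).train(train)
    return model, train, test


@pytest.fixture(scope="session")
def ranking_experiment():
    """Trained ranker + splits for the default detour/reversed fixture."""
    return _experiment(depth_matched=False)


@pytest.fixture(scope="session")
def depth_matched_experiment():
    """Trained ranker + splits for the depth-uninformative fixture."""
    return _experiment(depth_matched=True)
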