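"""Reaction networks, pathway trees and complete-DFS route enumeration.

Single-step reactions that share a source (typically one patent) are
assembled into a bipartite compound/reaction digraph.  Compounds appearing
only as products are *root nodes* — candidate targets — and a complete
depth-first traversal from each root enumerates every retrosynthesis
pathway embedded in the network.  A pathway is a rooted tree of reaction
nodes connected through intermediate compounds; leaves are reactions whose
reactants have no producing reaction in the network (treated as
purchasable starting materials).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

from .chem import Reaction

__all__ = [
    "PathwayNode",
    "Pathway",
    "PathwayGroup",
    "ReactionNetwork",
    "build_network",
    "find_roots",
    "enumerate_pathways",
    "pathway_depth",
    "filter_by_depth",
    "level_frontiers",
    "pathway_to_dict",
    "pathway_from_dict",
    "save_pathways",
    "load_pathways",
    "save_group",
    "load_group",
    "demo_network",
    "DEMO_LISTINGS",
]


@dataclass(frozen=True)
class PathwayNode:
    """A reaction node with the sub-syntheses of its non-terminal reactants."""

    reaction: Reaction
    children: tuple["PathwayNode", ...] = ()

    def validate(self) -> None:
        products = [c.reaction.product for c in self.children]
        if len(set(products)) != len(products):
            raise ValueError("children products are not pairwise distinct")
        for prod in products:
            if prod not in self.reaction.reactants:
                raise ValueError(
                    f"child product {prod!r} is not a reactant of its parent"
                )
        for child in self.children:
            child.validate()


@dataclass(frozen=True)
class Pathway:
    """A rooted retrosynthesis tree for one target compound.

    ``depth`` is always the recomputed longest root-to-leaf reaction chain.
    ``meta`` carries non-serialized generator bookkeeping (ignored by
    equality and I/O).
    """

    target: str
    root: PathwayNode
    source_id: str = ""
    label: str = "reference"  # or "alternative"
    pathway_id: str = ""
    meta: Optional[dict] = field(default=None, compare=False, repr=False)

    @property
    def depth(self) -> int:
        return _node_depth(self.root)

    def nodes(self) -> Iterator[PathwayNode]:
        """Pre-order traversal of reaction nodes."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def reactions(self) -> list[Reaction]:
        return [n.reaction for n in self.nodes()]

    def compounds(self) -> set[str]:
        """All compounds appearing in the pathway (target included)."""
        out: set[str] = set()
        for rxn in self.reactions():
            out.add(rxn.product)
            out.update(rxn.reactants)
        return out

    def leaf_compounds(self) -> set[str]:
        """Starting materials: reactants never produced inside the tree."""
        produced = {n.reaction.product for n in self.nodes()}
        out: set[str] = set()
        for rxn in self.reactions():
            out.update(r for r in rxn.reactants if r not in produced)
        return out

    def canonical_serialization(self) -> str:
        """Order-independent string identity of the tree."""
        return _canon(self.root)

    def validate(self) -> None:
        if self.label not in ("reference", "alternative"):
            raise ValueError(f"bad label {self.label!r}")
        if self.root.reaction.product != self.target:
            raise ValueError("root product does not match the target")
        keys_on_paths_ok = _no_repeat_on_path(self.root, frozenset())
        if not keys_on_paths_ok:
            raise ValueError("a reaction repeats on a root-to-leaf path")
        self.root.validate()


def _node_depth(node: PathwayNode) -> int:
    if not node.children:
        return 1
    return 1 + max(_node_depth(c) for c in node.children)


def _canon(node: PathwayNode) -> str:
    inner = ",".join(sorted(_canon(c) for c in node.children))
    prod, reactants = node.reaction.key
    return f"{prod}<{'.'.join(reactants)}[{inner}]"


def _no_repeat_on_path(node: PathwayNode, seen: frozenset) -> bool:
    if node.reaction.key in seen:
        return False
    seen = seen | {node.reaction.key}
    return all(_no_repeat_on_path(c, seen) for c in node.children)


@dataclass
class PathwayGroup:
    """One reference pathway plus alternatives sharing its target."""

    target: str
    reference: Pathway
    alternatives: list[Pathway]
    group_id: str = ""

    @property
    def source_id(self) -> str:
        return self.reference.source_id

    def pathways(self) -> list[Pathway]:
        return [self.reference, *self.alternatives]

    def validate(self) -> None:
        if self.reference.label != "reference":
            raise ValueError("group reference must carry label 'reference'")
        for p in self.pathways():
            if p.target != self.target:
                raise ValueError("group members do not share the target")
        for p in self.alternatives:
            if p.label != "alternative":
                raise ValueError("alternatives must carry label 'alternative'")


# ---------------------------------------------------------------------------
# Reaction networks


@dataclass
class ReactionNetwork:
    """Bipartite compound/reaction digraph for a single source.

    Edges run in the retrosynthetic direction: product -> reaction ->
    reactants.  ``graph`` is a networkx DiGraph whose compound nodes are
    the compound identifiers and whose reaction nodes are ``("rxn", i)``
    indices into ``reactions``.
    """

    compounds: set[str]
    reactions: list[Reaction]
    source_id: str
    graph: nx.DiGraph = field(repr=False, default_factory=nx.DiGraph)


def build_network(
    reactions: Sequence[Reaction], source_id: Optional[str] = None
) -> ReactionNetwork:
    """Deduplicated bipartite network from same-source reactions.

    Compounds are identified by exact (canonical) string equality and
    reactions by product + reactant set; mixed source ids raise.
    """
    sources = {r.source_id for r in reactions if r.source_id}
    if source_id is None:
        source_id = next(iter(sources)) if sources else ""
    if len(sources) > 1:
        raise ValueError(f"mixed source_ids in one network: {sorted(sources)}")
    seen: dict = {}
    for rxn in reactions:
        seen.setdefault(rxn.key, rxn)
    unique = list(seen.values())
    graph = nx.DiGraph()
    compounds: set[str] = set()
    for i, rxn in enumerate(unique):
        rnode = ("rxn", i)
        graph.add_node(rnode, kind="reaction")
        for c in {rxn.product, *rxn.reactants}:
            if c not in compounds:
                graph.add_node(c, kind="compound")
                compounds.add(c)
        graph.add_edge(rxn.product, rnode)
        for reactant in set(rxn.reactants):
            graph.add_edge(rnode, reactant)
    return ReactionNetwork(
        compounds=compounds, reactions=unique, source_id=source_id, graph=graph
    )


def find_roots(net: ReactionNetwork) -> set[str]:
    """Compounds appearing only as products (candidate pathway targets)."""
    return {
        c
        for c in net.compounds
        if net.graph.out_degree(c) > 0 and net.graph.in_degree(c) == 0
    }


def enumerate_pathways(net: ReactionNetwork, max_depth: int = 20) -> list[Pathway]:
    """Complete DFS enumeration of all pathways embedded in the network.

    Every expandable intermediate (one with at least one producing
    reaction) is expanded; when several reactions produce it, each choice
    spawns a separate pathway, and choices across the reactants of a
    multi-reactant step combine as a Cartesian product.  Expansion of a
    compound stops when every producing reaction already lies on the
    current root-to-leaf path (cycle guard), which makes all emitted trees
    acyclic.  Pathways deeper than ``max_depth`` are discarded; duplicates
    under canonical tree serialization are emitted once; output order is
    deterministic (target, then canonical serialization).
    """
    producers: dict[str, list[Reaction]] = {}
    for rxn in sorted(net.reactions, key=lambda r: r.key):
        producers.setdefault(rxn.product, []).append(rxn)

    def expand_compound(c: str, on_path: frozenset) -> list[Optional[PathwayNode]]:
        choices = [r for r in producers.get(c, ()) if r.key not in on_path]
        if not choices:
            return [None]
        out: list[Optional[PathwayNode]] = []
        for rxn in choices:
            out.extend(expand_reaction(rxn, on_path))
        return out

    def expand_reaction(rxn: Reaction, on_path: frozenset) -> list[PathwayNode]:
        on_path = on_path | {rxn.key}
        reactants = list(dict.fromkeys(rxn.reactants))
        options = [expand_compound(r, on_path) for r in reactants]
        return [
            PathwayNode(rxn, tuple(n for n in combo if n is not None))
            for combo in itertools.product(*options)
        ]

    out: list[Pathway] = []
    seen: set[str] = set()
    for root in sorted(find_roots(net)):
        for node in expand_compound(root, frozenset()):
            if node is None:
                continue
            p = Pathway(target=root, root=node, source_id=net.source_id)
            if p.depth > max_depth:
                continue
            canon = p.canonical_serialization()
            if canon in seen:
                continue
            seen.add(canon)
            out.append(p)
    out.sort(key=lambda p: (p.target, p.canonical_serialization()))
    return out


def pathway_depth(p: Pathway) -> int:
    """Number of reaction steps on the longest root-to-leaf chain."""
    return p.depth


def filter_by_depth(ps: Iterable[Pathway], lo: int = 4, hi: int = 10) -> list[Pathway]:
    """Keep pathways with ``lo <= depth <= hi``, order preserved."""
    if lo > hi:
        raise ValueError(f"lo={lo} exceeds hi={hi}")
    return [p for p in ps if lo <= p.depth <= hi]


def level_frontiers(p: Pathway) -> list[list[str]]:
    """Per-level reactant frontiers, starting with the target.

    Level 0 is ``[target]``; level i is the sorted union of reactants of
    the reaction nodes at tree depth i.  This is the compact listing
    format used when reporting enumerated routes.
    """
    levels: dict[int, set[str]] = {}

    def visit(node: PathwayNode, d: int) -> None:
        levels.setdefault(d, set()).update(node.reaction.reactants)
        for c in node.children:
            visit(c, d + 1)

    visit(p.root, 1)
    out = [[p.target]]
    for d in sorted(levels):
        out.append(sorted(levels[d], key=_listing_key))
    return out


def _listing_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


# ---------------------------------------------------------------------------
# JSON serialization


def _node_to_dict(node: PathwayNode) -> dict:
    return {
        "reaction": {
            "reactants": list(node.reaction.reactants),
            "reagents": list(node.reaction.reagents),
            "product": node.reaction.product,
        },
        "children": [_node_to_dict(c) for c in node.children],
    }


def _node_from_dict(d: dict, source_id: str) -> PathwayNode:
    rxn = d["reaction"]
    return PathwayNode(
        reaction=Reaction(
            reactants=tuple(rxn["reactants"]),
            reagents=tuple(rxn.get("reagents", ())),
            product=rxn["product"],
            source_id=source_id,
        ),
        children=tuple(_node_from_dict(c, source_id) for c in d.get("children", ())),
    )


def pathway_to_dict(p: Pathway) -> dict:
    out = {
        "target": p.target,
        "source_id": p.source_id,
        "label": p.label,
        "root": _node_to_dict(p.root),
    }
    if p.pathway_id:
        out["pathway_id"] = p.pathway_id
    return out


def pathway_from_dict(d: dict) -> Pathway:
    return Pathway(
        target=d["target"],
        source_id=d.get("source_id", ""),
        label=d.get("label", "reference"),
        pathway_id=d.get("pathway_id", ""),
        root=_node_from_dict(d["root"], d.get("source_id", "")),
    )


def save_pathways(ps: Pathway | Sequence[Pathway], path: str | Path) -> None:
    """Write one pathway or a list as UTF-8 JSON (lossless round-trip)."""
    payload = (
        pathway_to_dict(ps) if isinstance(ps, Pathway) else [pathway_to_dict(p) for p in ps]
    )
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_pathways(path: str | Path) -> list[Pathway]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if isinstance(data, dict):
        data = [data]
    return [pathway_from_dict(d) for d in data]


def save_group(g: PathwayGroup, path: str | Path) -> None:
    save_pathways(g.pathways(), path)


def load_group(path: str | Path, group_id: str = "") -> PathwayGroup:
    ps = load_pathways(path)
    refs = [p for p in ps if p.label == "reference"]
    if len(refs) != 1:
        raise ValueError(f"{path}: group must hold exactly one reference pathway")
    alts = [p for p in ps if p.label == "alternative"]
    g = PathwayGroup(
        target=refs[0].target,
        reference=refs[0],
        alternatives=alts,
        group_id=group_id or Path(path).stem,
    )
    g.validate()
    return g


# ---------------------------------------------------------------------------
# Packaged worked example

# A 20-compound, 15-reaction network of the kind extracted from a single
# process patent, using opaque numeric compound identifiers.  Its complete
# DFS enumeration yields exactly five depth-4 routes headed by the five
# root compounds 1, 2, 3, 9 and 13.
_DEMO_REACTIONS: list[tuple[str, tuple[str, ...]]] = [
    ("1", ("5", "6", "10")),
    ("2", ("6", "7", "11")),
    ("3", ("4", "11")),
    ("9", ("8", "11")),
    ("13", ("11", "12")),
    ("5", ("14",)),
    ("7", ("15",)),
    ("4", ("15",)),
    ("8", ("15",)),
    ("12", ("15",)),
    ("14", ("16", "17")),
    ("15", ("17", "18")),
    ("16", ("19", "20")),
    ("17", ("19", "20")),
    ("18", ("19", "20")),
]

# Expected frontier listings of the five routes, keyed by target.
DEMO_LISTINGS: dict[str, list[list[str]]] = {
    "1": [["1"], ["5", "6", "10"], ["14"], ["16", "17"], ["19", "20"]],
    "2": [["2"], ["6", "7", "11"], ["15"], ["17", "18"], ["19", "20"]],
    "3": [["3"], ["4", "11"], ["15"], ["17", "18"], ["19", "20"]],
    "9": [["9"], ["8", "11"], ["15"], ["17", "18"], ["19", "20"]],
    "13": [["13"], ["11", "12"], ["15"], ["17", "18"], ["19", "20"]],
}


def demo_network() -> ReactionNetwork:
    """The packaged worked-example patent-style reaction network."""
    reactions = [
        Reaction(reactants=rs, product=p, source_id="DEMO-PATENT")
        for p, rs in _DEMO_REACTIONS
    ]
    return build_network(reactions, source_id="DEMO-PATENT")
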