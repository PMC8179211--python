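"""Seeded generator of pathway groups with controlled strategy structure.

The generator emulates the ranking setup of a curated pathway database —
one practiced reference route plus machine-generated alternatives per
target — with no external data.  Targets are linear assemblies of small
fragments (alkyl / para-phenylene cores) joined by amide, ether or ester
linkages; a route is an assembly order (a binary bracketing of the
fragment sequence) plus functional-group bookkeeping steps.  All molecule
strings are assembled from a composable SMILES fragment grammar and every
reaction is RDKit-validated, so the chemistry is syntactically real even
though the transformations are grammar-level rewrites rather than
validated wet chemistry: the object under study is strategy *structure*.

Every reference route carries a protection motif: one fragment holds a
spectator secondary amine that is Boc-protected before the couplings and
deprotected in the final step.  Corruptions then mirror the failure modes
of unguided route search:

* ``detour_pair`` — a nonproductive add/remove pair of reactions on an
  intermediate (depth +2, one extra compound, composes to identity);
* ``reversed_protection`` — deprotection moved before the couplings, so
  the protection becomes pointless and the couplings run on the free
  amine (depth-preserving, the classic selectivity flaw);
* ``step_order_swap`` — re-association of two consecutive assembly steps
  (a strategy-preserving near-duplicate; reaction types unchanged).

In ``depth_matched`` mode alternatives are fresh independent assembly
orders of the same target (route depth drawn i.i.d. with the reference's)
corrupted with the depth-preserving flaw, so pathway depth carries no
ranking signal and only strategy content separates the classes.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .chem import Reaction, canonicalize
from .network import Pathway, PathwayGroup, PathwayNode, save_group

__all__ = [
    "FixtureSpec",
    "SkipCorruption",
    "gen_molecules",
    "gen_reference_pathway",
    "corrupt",
    "gen_group",
    "gen_dataset",
    "write_dataset",
]

BOC_N = "N(C(=O)OC(C)(C)C)"
PHENYLENE = "c1ccc(cc1)"

# linker name -> (in-product link string, left reactant suffix, right prefix)
LINKERS: dict[str, tuple[str, str, str]] = {
    "amide": ("C(=O)N", "C(=O)O", "N"),
    "ether": ("O", "O", "Br"),
    "ester": ("C(=O)O", "C(=O)O", "O"),
}


class SkipCorruption(Exception):
    """A corruption kind does not apply to this pathway (reported, skipped)."""


@dataclass(frozen=True)
class Fragment:
    """A composable molecule fragment; the spectator variant carries the
    secondary amine targeted by Boc protection."""

    body: str
    spectator_n: bool = False

    def render(self, boc: bool) -> str:
        if boc and self.spectator_n:
            return self.body.replace("N", BOC_N, 1)
        return self.body


@dataclass(frozen=True)
class TargetSpec:
    """A target molecule as a fragment sequence with linkages."""

    fragments: tuple[Fragment, ...]
    linkers: tuple[str, ...]
    spectator_idx: int


@dataclass(frozen=True)
class RouteSpec:
    """One route to a target: assembly order + decorations."""

    bracket: object  # nested (left, right) tuples over fragment indices
    protection: str = "early"  # 'early' | 'reversed' | 'none'
    unary_leaves: tuple[int, ...] = ()
    # detour sites: (bracket path, decoration variant) pairs
    detours: tuple[tuple[tuple[int, ...], int], ...] = ()


@dataclass
class FixtureSpec:
    """Study conditions of the synthetic ranking experiment."""

    n_groups: int = 50
    depth_range: tuple[int, int] = (4, 10)
    alternatives_per_group: tuple[int, int] = (5, 20)
    kinds: tuple[str, ...] = ("detour_pair", "reversed_protection", "step_order_swap")
    alphabet_size: int = 24
    seed: int = 0
    depth_matched: bool = False
    unary_prob: float = 0.25

    def __post_init__(self) -> None:
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] < 3:
            raise ValueError("depth_range must be non-empty with lo >= 3")
        if self.alternatives_per_group[0] > self.alternatives_per_group[1]:
            raise ValueError("alternatives_per_group range is empty")
        if not self.kinds:
            raise ValueError("at least one corruption kind must be enabled")


# ---------------------------------------------------------------------------
# Fragment alphabet and standalone molecule generator


def _plain_bodies() -> list[str]:
    chains = ("C", "CC", "CCC")
    tails = ("", "C", "CC", "CCC")
    out = set(chains)
    for a, b in itertools.product(chains, tails):
        out.add(a + PHENYLENE + b)
        for c in tails:
            out.add(a + PHENYLENE + b + PHENYLENE + c)
    return sorted(out)


def _spectator_bodies() -> list[str]:
    return ["C" * a + "N" + "C" * b for a in (1, 2) for b in (1, 2)]


def _alphabet(spec: FixtureSpec, rng: np.random.Generator
              ) -> tuple[list[Fragment], list[Fragment]]:
    pool = _plain_bodies()
    take = min(spec.alphabet_size, len(pool))
    idx = sorted(rng.choice(len(pool), size=take, replace=False))
    plain = [Fragment(pool[i]) for i in idx]
    spectators = [Fragment(b, spectator_n=True) for b in _spectator_bodies()]
    return plain, spectators


def gen_molecules(n: int, seed: int = 0) -> list[str]:
    """``n`` distinct canonical SMILES from the fragment grammar.

    Alkyl/aryl cores optionally decorated with halide, amine, boronate,
    ester or Boc-amine termini.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    decorations = ["", "Br", "N", "B(O)O", "C(=O)OC", "NC(=O)OC(C)(C)C"]
    bodies = _plain_bodies()
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 300 * n:
            raise ValueError(f"fragment grammar cannot yield {n} distinct molecules")
        body = bodies[rng.integers(len(bodies))]
        dec = decorations[rng.integers(len(decorations))]
        smi = canonicalize(body + dec)
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
    return out


# ---------------------------------------------------------------------------
# Bracket (assembly order) machinery


def _leaves(bracket) -> list[int]:
    if isinstance(bracket, int):
        return [bracket]
    return _leaves(bracket[0]) + _leaves(bracket[1])


def _bracket_depth(bracket) -> int:
    if isinstance(bracket, int):
        return 0
    return 1 + max(_bracket_depth(bracket[0]), _bracket_depth(bracket[1]))


def _feasible(n: int, d: int) -> bool:
    """Can a bracketing of n leaves have depth exactly d?"""
    if n == 1:
        return d == 0
    return int(np.ceil(np.log2(n))) <= d <= n - 1


def _gen_bracket(lo: int, hi: int, d: int, deep_leaf: int,
                 rng: np.random.Generator):
    """Random bracketing of fragments [lo..hi] with depth exactly ``d``,
    placing ``deep_leaf`` on a maximal-depth chain."""
    n = hi - lo + 1
    if n == 1:
        return lo
    splits = []
    for m in range(lo, hi):
        nl, nr = m - lo + 1, hi - m
        deep_left = deep_leaf <= m
        n_deep, n_other = (nl, nr) if deep_left else (nr, nl)
        if not _feasible(n_deep, d - 1):
            continue
        others = [dd for dd in range(0, d) if _feasible(n_other, dd)]
        if others:
            splits.append((m, deep_left, others))
    if not splits:
        raise ValueError(f"no bracketing of {n} leaves with depth {d}")
    m, deep_left, others = splits[rng.integers(len(splits))]
    d_other = others[rng.integers(len(others))]
    if deep_left:
        left = _gen_bracket(lo, m, d - 1, deep_leaf, rng)
        right = _gen_bracket(m + 1, hi, d_other, _leaves_any(m + 1, hi, rng), rng)
    else:
        left = _gen_bracket(lo, m, d_other, _leaves_any(lo, m, rng), rng)
        right = _gen_bracket(m + 1, hi, d - 1, deep_leaf, rng)
    return (left, right)


def _leaves_any(lo: int, hi: int, rng: np.random.Generator) -> int:
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# Molecule string assembly


def _span_string(ts: TargetSpec, lo: int, hi: int, boc: bool) -> str:
    parts = []
    for i in range(lo, hi + 1):
        parts.append(ts.fragments[i].render(boc))
        if i < hi:
            parts.append(LINKERS[ts.linkers[i]][0])
    return "".join(parts)


def _precursor(m: str) -> str:
    """One plausible refunctionalization precursor of a molecule string."""
    if m.endswith("C(=O)O"):
        return m[: -len("C(=O)O")] + "CO"  # acid from alcohol oxidation
    if m.endswith("O"):
        return m[:-1] + "C(=O)OC"  # alcohol from ester reduction
    if m.startswith("Br"):
        return m[2:]  # halide from bromination
    if m.startswith("N"):
        return "O" + m[1:]  # amine from alcohol amination
    return m + "C(=O)O"  # bare core from decarboxylation


def _detour_form(m: str, variant: int = 0) -> str:
    """Removable decoration for the nonproductive detour pair."""
    if m.endswith("O"):
        # tert-butyl or ethyl capping of the terminal O-H
        return m + ("C(C)(C)C" if variant == 0 else "CC")
    # terminal bromination or hydroxymethylation
    return m + ("Br" if variant == 0 else "CO")


# ---------------------------------------------------------------------------
# Pathway construction


class _Builder:
    def __init__(self, ts: TargetSpec, rs: RouteSpec, source_id: str):
        self.ts, self.rs, self.source_id = ts, rs, source_id
        self.detours: dict[tuple[int, ...], list[int]] = {}
        for path, variant in rs.detours:
            self.detours.setdefault(tuple(path), []).append(variant)

    def _rxn(self, reactants: Sequence[str], product: str) -> Reaction:
        return Reaction.from_smiles(reactants, product, source_id=self.source_id)

    def _wrap_detour(self, node: Optional[PathwayNode], prod: str,
                     variant: int) -> PathwayNode:
        dec = _detour_form(prod, variant)
        mid = PathwayNode(self._rxn([prod], dec), (node,) if node else ())
        return PathwayNode(self._rxn([dec], prod), (mid,))

    def _leaf_chain(self, idx: int, prefix: str, suffix: str, boc: bool
                    ) -> tuple[Optional[PathwayNode], str]:
        frag = self.ts.fragments[idx]
        is_spec = idx == self.ts.spectator_idx and self.rs.protection != "none"
        free = prefix + frag.render(False) + suffix
        node: Optional[PathwayNode] = None
        if idx in self.rs.unary_leaves:
            node = PathwayNode(self._rxn([_precursor(free)], free))
        if not is_spec:
            return node, free
        protected = prefix + frag.render(True) + suffix
        prot = PathwayNode(self._rxn([free], protected), (node,) if node else ())
        if self.rs.protection == "early":
            return prot, protected  # consumed Boc-protected; freed at the root
        deprot = PathwayNode(self._rxn([protected], free), (prot,))
        return deprot, free  # 'reversed': pointless protect/deprotect pair

    def _node(self, bracket, prefix: str, suffix: str, boc: bool,
              path: tuple[int, ...]) -> tuple[Optional[PathwayNode], str]:
        if isinstance(bracket, int):
            node, prod = self._leaf_chain(bracket, prefix, suffix, boc)
        else:
            left, right = bracket
            m = max(_leaves(left))
            _, lsuf, rpre = LINKERS[self.ts.linkers[m]]
            lnode, lp = self._node(left, prefix, lsuf, boc, path + (0,))
            rnode, rp = self._node(right, rpre, suffix, boc, path + (1,))
            lo, hi = min(_leaves(bracket)), max(_leaves(bracket))
            span_boc = boc and lo <= self.ts.spectator_idx <= hi
            prod = prefix + _span_string(self.ts, lo, hi, span_boc) + suffix
            children = tuple(n for n in (lnode, rnode) if n is not None)
            node = PathwayNode(self._rxn([lp, rp], prod), children)
        for variant in sorted(self.detours.get(path, ())):
            node = self._wrap_detour(node, prod, variant)
        return node, prod

    def build(self, label: str, pathway_id: str, group_id: str = "") -> Pathway:
        rs = self.rs
        boc = rs.protection == "early"
        body, prod = self._node(rs.bracket, "", "", boc, ())
        assert body is not None
        if rs.protection == "early":
            free = _span_string(self.ts, 0, len(self.ts.fragments) - 1, False)
            root = PathwayNode(self._rxn([prod], free), (body,))
            target = free
        else:
            root, target = body, prod
        p = Pathway(
            target=canonicalize(target),
            root=root,
            source_id=self.source_id,
            label=label,
            pathway_id=pathway_id,
            meta={"ts": self.ts, "rs": rs, "group_id": group_id},
        )
        p.validate()
        return p


def _build(ts: TargetSpec, rs: RouteSpec, source_id: str, label: str,
           pathway_id: str, group_id: str = "") -> Pathway:
    return _Builder(ts, rs, source_id).build(label, pathway_id, group_id)


# ---------------------------------------------------------------------------
# Target and route sampling


def _gen_target(spec: FixtureSpec, k: int, rng: np.random.Generator) -> TargetSpec:
    plain, spectators = _alphabet(spec, rng)
    picks = rng.choice(len(plain), size=k - 1, replace=False)
    frags = [plain[i] for i in picks]
    spectator_idx = int(rng.integers(0, k))
    frags.insert(spectator_idx, spectators[rng.integers(len(spectators))])
    names = list(LINKERS)
    linkers = tuple(names[rng.integers(len(names))] for _ in range(k - 1))
    return TargetSpec(tuple(frags), linkers, spectator_idx)


def _achievable_depths(k: int, depth_range: tuple[int, int]) -> list[int]:
    """Route depths realizable for a k-fragment target (couplings + motif)."""
    lo = int(np.ceil(np.log2(k))) + 2
    hi = k + 1
    return [d for d in range(lo, hi + 1) if depth_range[0] <= d <= depth_range[1]]


def _gen_route(ts: TargetSpec, spec: FixtureSpec, rng: np.random.Generator,
               depth: Optional[int] = None) -> RouteSpec:
    k = len(ts.fragments)
    choices = _achievable_depths(k, spec.depth_range)
    if depth is None:
        depth = choices[rng.integers(len(choices))]
    bracket = _gen_bracket(0, k - 1, depth - 2, ts.spectator_idx, rng)
    unary = tuple(
        i for i in range(k)
        if i != ts.spectator_idx and rng.random() < spec.unary_prob
    )
    return RouteSpec(bracket=bracket, protection="early", unary_leaves=unary)


def gen_reference_pathway(
    spec: FixtureSpec,
    seed: Optional[int] = None,
    source_id: str = "SRC0",
    pathway_id: str = "ref",
) -> Pathway:
    """One clean reference route sampled under the fixture conditions."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k_lo, k_hi = _k_range(spec)
    k = int(rng.integers(k_lo, k_hi + 1))
    ts = _gen_target(spec, k, rng)
    rs = _gen_route(ts, spec, rng)
    return _build(ts, rs, source_id, "reference", pathway_id)


def _k_range(spec: FixtureSpec) -> tuple[int, int]:
    """Fragment counts whose achievable route depths intersect depth_range."""
    lo_d, hi_d = spec.depth_range
    ks = [k for k in range(3, 13) if _achievable_depths(k, (lo_d, hi_d))]
    return min(ks), max(ks)


# ---------------------------------------------------------------------------
# Corruptions


def _rotations(bracket, path=()):  # all (path, rotated) re-associations
    out = []
    if isinstance(bracket, int):
        return out
    left, right = bracket
    if not isinstance(left, int):
        out.append((path, (left[0], (left[1], right))))
    if not isinstance(right, int):
        out.append((path, ((left, right[0]), right[1])))
    out += [(p, r) for p, r in _rotations(left, path + (0,))]
    out += [(p, r) for p, r in _rotations(right, path + (1,))]
    return out


def _replace_at(bracket, path, new):
    if not path:
        return new
    left, right = bracket
    if path[0] == 0:
        return (_replace_at(left, path[1:], new), right)
    return (left, _replace_at(right, path[1:], new))


def _spectator_path(bracket, spectator_idx, path=()):
    if isinstance(bracket, int):
        return path
    left, right = bracket
    if spectator_idx in _leaves(left):
        return _spectator_path(left, spectator_idx, path + (0,))
    return _spectator_path(right, spectator_idx, path + (1,))


def corrupt(p: Pathway, kind: str, seed: int = 0) -> Pathway:
    """Derive a corrupted alternative from a generated pathway.

    Raises :class:`SkipCorruption` when the kind does not apply (pathway
    too small, protection already reversed, no detour site left).
    Requires the generator metadata attached to fixture pathways.
    """
    if p.meta is None or "rs" not in p.meta:
        raise SkipCorruption("pathway lacks generator route metadata")
    ts: TargetSpec = p.meta["ts"]
    rs: RouteSpec = p.meta["rs"]
    rng = np.random.default_rng(seed)
    if kind == "detour_pair":
        spath = _spectator_path(rs.bracket, ts.spectator_idx)
        candidates = [
            (spath[:i], v)
            for i in range(len(spath) + 1)
            for v in (0, 1)
            if (spath[:i], v) not in rs.detours
        ]
        if not candidates:
            raise SkipCorruption("no detour site left on the deepest chain")
        site = candidates[rng.integers(len(candidates))]
        new_rs = replace(rs, detours=rs.detours + (site,))
    elif kind == "reversed_protection":
        if rs.protection != "early":
            raise SkipCorruption("protection motif absent or already reversed")
        new_rs = replace(rs, protection="reversed")
    elif kind == "step_order_swap":
        rots = _rotations(rs.bracket)
        if not rots:
            raise SkipCorruption("pathway too small to re-associate steps")
        path, rotated = rots[rng.integers(len(rots))]
        new_rs = replace(rs, bracket=_replace_at(rs.bracket, path, rotated))
    else:
        raise ValueError(f"unknown corruption kind {kind!r}")
    return _build(ts, new_rs, p.source_id, "alternative",
                  f"{p.pathway_id}|{kind}@{seed}", p.meta.get("group_id", ""))


# ---------------------------------------------------------------------------
# Groups and datasets


def gen_group(spec: FixtureSpec, group_index: int = 0,
              rng: Optional[np.random.Generator] = None) -> PathwayGroup:
    """One reference + corrupted alternatives sharing its target."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    gid = f"G{group_index:04d}"
    source_id = f"SRC{group_index:04d}"
    k_lo, k_hi = _k_range(spec)
    if spec.depth_matched:
        # small targets admit too few distinct assembly orders to build a
        # full group of independent same-target routes
        k_lo = min(max(k_lo, 5), k_hi)
    k = int(rng.integers(k_lo, k_hi + 1))
    ts = _gen_target(spec, k, rng)
    ref_rs = _gen_route(ts, spec, rng)
    ref = _build(ts, ref_rs, source_id, "reference", f"{gid}/ref", gid)
    lo, hi = spec.alternatives_per_group
    n_alts = int(rng.integers(lo, hi + 1))
    alts: list[Pathway] = []
    seen = {ref.canonical_serialization()}
    attempts = 0
    while len(alts) < n_alts:
        attempts += 1
        if attempts > 60 * n_alts:
            raise RuntimeError(
                f"could not assemble {n_alts} distinct alternatives for {gid}"
            )
        try:
            if spec.depth_matched:
                alt_rs = replace(_gen_route(ts, spec, rng), protection="reversed")
                cand = _build(ts, alt_rs, source_id, "alternative",
                              f"{gid}/alt{len(alts):03d}", gid)
            else:
                kind = spec.kinds[rng.integers(len(spec.kinds))]
                cand = corrupt(ref, kind, seed=int(rng.integers(2**31 - 1)))
                for _ in range(2):  # higher-order corruptions for variety
                    if rng.random() >= 0.35:
                        break
                    kind2 = spec.kinds[rng.integers(len(spec.kinds))]
                    try:
                        cand = corrupt(cand, kind2, seed=int(rng.integers(2**31 - 1)))
                    except SkipCorruption:
                        pass
        except SkipCorruption:
            continue
        canon = cand.canonical_serialization()
        if canon in seen:
            continue
        seen.add(canon)
        alts.append(replace(cand, pathway_id=f"{gid}/alt{len(alts):03d}"))
    group = PathwayGroup(target=ref.target, reference=ref, alternatives=alts,
                         group_id=gid)
    group.validate()
    return group


def gen_dataset(spec: FixtureSpec) -> list[PathwayGroup]:
    """All groups of the fixture, byte-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    return [gen_group(spec, i, rng) for i in range(spec.n_groups)]


def write_dataset(groups: Sequence[PathwayGroup], outdir: str | Path,
                  seed: Optional[int] = None) -> None:
    """One pathway-JSON file per group plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group_id", "target", "n_alternatives", "source_id", "seed"])
        for g in groups:
            save_group(g, outdir / f"{g.group_id}.json")
            writer.writerow([g.group_id, g.target, len(g.alternatives),
                             g.source_id, "" if seed is None else seed])
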