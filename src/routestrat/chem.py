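"""Reaction records, canonicalization, reagent separation and featurization.

A retrosynthesis pathway is scored at the level of its single-step
reactions, each represented by a :class:`Reaction` (reactants, reagents,
one main product).  For the neural encoder every reaction node is turned
into a pair of Morgan fingerprints: a 2048-bit radius-2 bit vector of the
product, and a signed count-difference fingerprint of the transformation
(product counts minus the summed reactant counts, reagents excluded).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

FP_BITS = 2048
FP_RADIUS = 2
COUNT_CLIP = 255

__all__ = [
    "Reaction",
    "NodeFeatures",
    "canonicalize",
    "split_reagents",
    "product_fingerprint",
    "reaction_fingerprint",
    "featurize",
    "read_reactions",
    "write_reactions",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


@functools.lru_cache(maxsize=200_000)
def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES form (idempotent).

    Raises :class:`SmilesParseError` naming the offending string.
    """
    return Chem.MolToSmiles(_mol(smiles))


@dataclass(frozen=True)
class Reaction:
    """One single-step reaction: reactants and reagents giving one product.

    The plain constructor trusts its caller (compound fields may be opaque
    identifiers when working with abstract reaction networks); use
    :meth:`from_smiles` to canonicalize and validate real chemistry.
    """

    reactants: tuple[str, ...]
    product: str
    reagents: tuple[str, ...] = ()
    source_id: str = ""
    atom_mapped_smiles: Optional[str] = None

    @classmethod
    def from_smiles(
        cls,
        reactants: Sequence[str],
        product: str,
        reagents: Sequence[str] = (),
        source_id: str = "",
        atom_mapped_smiles: Optional[str] = None,
    ) -> "Reaction":
        rxn = cls(
            reactants=tuple(canonicalize(s) for s in reactants),
            product=canonicalize(product),
            reagents=tuple(canonicalize(s) for s in reagents),
            source_id=source_id,
            atom_mapped_smiles=atom_mapped_smiles,
        )
        rxn.validate()
        return rxn

    def validate(self) -> None:
        if not self.product:
            raise ValueError("reaction has an empty product")
        if not self.reactants:
            raise ValueError("reaction has no reactants")
        if self.product in self.reactants and len(self.reactants) > 1:
            # a strict identity step (single reactant == product) is kept
            # representable for degenerate tests; a product repeated among
            # several reactants is malformed.
            raise ValueError("product appears among multiple reactants")

    @property
    def key(self) -> tuple[str, tuple[str, ...]]:
        """Identity of the transformation: product + sorted reactant set."""
        return (self.product, tuple(sorted(set(self.reactants))))

    def smiles(self) -> str:
        """Reaction SMILES ``reactants>reagents>product``."""
        return ">".join(
            [".".join(self.reactants), ".".join(self.reagents), self.product]
        )


@dataclass(frozen=True)
class NodeFeatures:
    """Featurized reaction node: product bits + signed reaction counts."""

    product_fp: np.ndarray  # uint8, length 2048, entries in {0, 1}
    reaction_fp: np.ndarray  # int32, length 2048, clipped to +-255

    def concat(self) -> np.ndarray:
        """The 4096-long float input of the reaction embedding network."""
        return np.concatenate(
            [self.product_fp.astype(np.float32), self.reaction_fp.astype(np.float32)]
        )

    def __eq__(self, other: object) -> bool:  # array fields need explicit eq
        return (
            isinstance(other, NodeFeatures)
            and np.array_equal(self.product_fp, other.product_fp)
            and np.array_equal(self.reaction_fp, other.reaction_fp)
        )


_generator = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


@functools.lru_cache(maxsize=200_000)
def _count_fp(canonical_smiles: str) -> np.ndarray:
    """Count-based Morgan fingerprint folded to ``FP_BITS``."""
    fp = _generator.GetCountFingerprint(_mol(canonical_smiles))
    arr = np.zeros(FP_BITS, dtype=np.int32)
    for idx, count in fp.GetNonzeroElements().items():
        arr[idx] = count
    return arr


@functools.lru_cache(maxsize=200_000)
def _bit_fp(canonical_smiles: str) -> np.ndarray:
    fp = _generator.GetFingerprint(_mol(canonical_smiles))
    arr = np.zeros(FP_BITS, dtype=np.uint8)
    for idx in fp.GetOnBits():
        arr[idx] = 1
    return arr


def product_fingerprint(product: str) -> np.ndarray:
    """2048-bit radius-2 Morgan bit vector of a molecule."""
    return _bit_fp(canonicalize(product)).copy()


def reaction_fingerprint(rxn: Reaction) -> np.ndarray:
    """Signed difference fingerprint of the transformation.

    Count fingerprint of the product minus the element-wise sum over all
    reactants, folded to 2048 and clipped to [-255, 255].  Reagents are
    excluded so the vector depends only on the bond-forming chemistry.
    """
    acc = _count_fp(canonicalize(rxn.product)).astype(np.int64)
    for r in rxn.reactants:
        acc = acc - _count_fp(canonicalize(r))
    return np.clip(acc, -COUNT_CLIP, COUNT_CLIP).astype(np.int32)


def featurize(rxn: Reaction) -> NodeFeatures:
    """Bundle product and reaction fingerprints for one reaction node."""
    return NodeFeatures(
        product_fp=product_fingerprint(rxn.product),
        reaction_fp=reaction_fingerprint(rxn),
    )


def _main_product(product_part: str) -> str:
    """Largest fragment by heavy-atom count is the main product."""
    frags = product_part.split(".")
    mols = [(frag, _mol(frag)) for frag in frags]
    frag, _ = max(mols, key=lambda t: t[1].GetNumHeavyAtoms())
    return frag


def _map_numbers(mol: Chem.Mol) -> set[int]:
    return {a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0}


def _strip_maps(mol: Chem.Mol) -> str:
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def split_reagents(rxn: Reaction) -> Reaction:
    """Separate reactants from reagents using atom-map numbers.

    Every left-hand species contributing at least one mapped atom to the
    product stays a reactant; all others become reagents.  Requires
    ``atom_mapped_smiles``; a product without mapped atoms fails reaction
    validation and is rejected.
    """
    if rxn.atom_mapped_smiles is None:
        raise ValueError("split_reagents requires atom_mapped_smiles")
    try:
        left, middle, right = rxn.atom_mapped_smiles.split(">")
    except ValueError as exc:
        raise ValueError(
            f"malformed reaction SMILES: {rxn.atom_mapped_smiles!r}"
        ) from exc
    product_frag = _main_product(right)
    product_mol = _mol(product_frag)
    product_maps = _map_numbers(product_mol)
    if not product_maps:
        raise ValueError(
            "reaction rejected: product carries no atom-map numbers "
            f"({rxn.atom_mapped_smiles!r})"
        )
    reactants: list[str] = []
    reagents = [canonicalize(s) for s in middle.split(".") if s]
    for species in left.split("."):
        mol = _mol(species)
        if _map_numbers(mol) & product_maps:
            reactants.append(canonicalize(_strip_maps(mol)))
        else:
            reagents.append(canonicalize(_strip_maps(mol)))
    out = replace(
        rxn,
        reactants=tuple(reactants),
        reagents=tuple(reagents),
        product=canonicalize(_strip_maps(product_mol)),
    )
    out.validate()
    return out


def read_reactions(path: str | Path) -> Iterator[Reaction]:
    """Read ``reactants>reagents>products<TAB>source_id`` records.

    UTF-8 text, one record per line, ``#`` comment lines ignored.  Records
    with atom maps are reagent-separated via :func:`split_reagents`.
    """
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rxn_smiles, source_id = line.split("\t")
                left, middle, right = rxn_smiles.split(">")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record") from exc
            mapped = any(":" in part for part in (left, right))
            rxn = Reaction.from_smiles(
                reactants=[_strip_maps(_mol(s)) for s in left.split(".") if s],
                product=_strip_maps(_mol(_main_product(right))),
                reagents=[_strip_maps(_mol(s)) for s in middle.split(".") if s],
                source_id=source_id,
                atom_mapped_smiles=rxn_smiles if mapped else None,
            )
            yield split_reagents(rxn) if mapped else rxn


def write_reactions(reactions: Iterable[Reaction], path: str | Path) -> None:
    """Inverse of :func:`read_reactions`."""
    with open(path, "w", encoding="utf-8") as handle:
        for rxn in reactions:
            smiles = rxn.atom_mapped_smiles or rxn.smiles()
            handle.write(f"{smiles}\t{rxn.source_id}\n")
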