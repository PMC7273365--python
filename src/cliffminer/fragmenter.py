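"""Single-cut fragmentation into H-capped cores and labeled substituents.

Every acyclic single bond between two heavy atoms is cut in turn, giving
exactly two fragments. A cut qualifies when the larger fragment (the core)
has at least twice as many heavy atoms as the smaller one (the
substituent) and the substituent has at most 13 heavy atoms. The core is
capped with hydrogen at the cut position (R -> H) and re-canonicalized;
the substituent keeps a dummy-atom attachment point (``*``).

Attachment positions are compared by *symmetry class*: the canonical
atom-rank equivalence class of the capped atom within the capped core.
Topologically equivalent positions (e.g. all six carbons of benzene)
share one class, so "different sites" below always means topologically
distinguishable sites.
"""

from __future__ import annotations

from ast import literal_eval
from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem

from .data_ingest import CompoundActivity
from .errors import StructureError


@dataclass(frozen=True, order=True)
class Fragmentation:
    """One qualifying single-cut decomposition of a compound."""

    compound_id: str
    core_smiles: str
    substituent_smiles: str
    position_class: int
    sub_heavy_atoms: int
    core_heavy_atoms: int


def _as_mol(structure: str | Chem.Mol) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(structure)
    return mol


def enumerate_cuts(structure: str | Chem.Mol) -> list[int]:
    """Bond indices of all acyclic single bonds between two heavy atoms."""
    mol = _as_mol(structure)
    cuts = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetBeginAtom().GetAtomicNum() <= 1:
            continue
        if bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        cuts.append(bond.GetIdx())
    return cuts


def apply_size_rules(
    core_heavy: int,
    sub_heavy: int,
    core_ratio: float = 2.0,
    max_sub_atoms: int = 13,
) -> bool:
    """True iff the core/substituent split satisfies the size restrictions.

    The core must carry at least ``core_ratio`` times the substituent's
    heavy atoms and the substituent at most ``max_sub_atoms`` heavy atoms.
    """
    return core_heavy >= core_ratio * sub_heavy and sub_heavy <= max_sub_atoms


def _heavy_atoms(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _drop_dummy_and_canonicalize(piece: Chem.Mol) -> tuple[str, int]:
    """Replace the dummy attachment by an implicit H; return (smiles, capped atom).

    The returned atom index refers to the molecule obtained by re-parsing
    the returned canonical SMILES.
    """
    em = Chem.RWMol(piece)
    dummy = next(a.GetIdx() for a in em.GetAtoms() if a.GetAtomicNum() == 0)
    capped = em.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
    em.RemoveAtom(dummy)
    if capped > dummy:
        capped -= 1
    core = em.GetMol()
    Chem.SanitizeMol(core)
    # stereocenters whose configuration the cut destroyed become unassigned
    Chem.AssignStereochemistry(core, cleanIt=True, force=True)
    smiles = Chem.MolToSmiles(core)
    order = literal_eval(core.GetProp("_smilesAtomOutputOrder"))
    return smiles, list(order).index(capped)


@lru_cache(maxsize=65536)
def _symmetry_classes(canonical_smiles: str) -> tuple[int, ...]:
    """Canonical-rank symmetry classes of a molecule given by canonical SMILES."""
    mol = Chem.MolFromSmiles(canonical_smiles)
    return tuple(Chem.CanonicalRankAtoms(mol, breakTies=False))


def cap_and_classify(
    structure: str | Chem.Mol,
    bond_idx: int,
    compound_id: str = "",
    core_ratio: float = 2.0,
    max_sub_atoms: int = 13,
) -> Fragmentation | None:
    """Cut one bond, cap the core with H, and classify the attachment position.

    Returns ``None`` when the cut violates the size rules (including the
    degenerate equal-halves case, which can never satisfy a 2:1 ratio).
    """
    mol = _as_mol(structure)
    cut = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True, dummyLabels=[(0, 0)])
    pieces = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
    if len(pieces) != 2:  # ring bond slipped through: not a valid cut
        return None
    sizes = [_heavy_atoms(p) for p in pieces]
    core_i = 0 if sizes[0] >= sizes[1] else 1
    core_heavy, sub_heavy = sizes[core_i], sizes[1 - core_i]
    if not apply_size_rules(core_heavy, sub_heavy, core_ratio, max_sub_atoms):
        return None

    core_smiles, capped_pos = _drop_dummy_and_canonicalize(pieces[core_i])
    position_class = _symmetry_classes(core_smiles)[capped_pos]

    sub = Chem.Mol(pieces[1 - core_i])
    Chem.AssignStereochemistry(sub, cleanIt=True, force=True)
    sub_smiles = Chem.MolToSmiles(sub)
    return Fragmentation(
        compound_id=compound_id,
        core_smiles=core_smiles,
        substituent_smiles=sub_smiles,
        position_class=position_class,
        sub_heavy_atoms=sub_heavy,
        core_heavy_atoms=core_heavy,
    )


def fragment_compound(
    activity: CompoundActivity | str,
    compound_id: str | None = None,
    core_ratio: float = 2.0,
    max_sub_atoms: int = 13,
) -> list[Fragmentation]:
    """All qualifying decompositions of one compound, deduplicated and sorted.

    Accepts either a :class:`CompoundActivity` or a raw SMILES plus
    ``compound_id``. Duplicate (core, substituent, position) triples —
    e.g. the two equivalent cuts of para-xylene — collapse to one entry.
    """
    if isinstance(activity, CompoundActivity):
        smiles, cid = activity.canonical_smiles, activity.compound_id
    else:
        smiles, cid = activity, compound_id or ""
    mol = _as_mol(smiles)
    seen: set[tuple[str, str, int]] = set()
    out: list[Fragmentation] = []
    for bond_idx in enumerate_cuts(mol):
        frag = cap_and_classify(mol, bond_idx, cid, core_ratio, max_sub_atoms)
        if frag is None:
            continue
        key = (frag.core_smiles, frag.substituent_smiles, frag.position_class)
        if key in seen:
            continue
        seen.add(key)
        out.append(frag)
    out.sort()
    return out
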