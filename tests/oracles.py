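"""Independent brute-force oracles and a random small-molecule generator.

The fragmentation oracle deletes every acyclic single bond in turn with
plain RWMol editing and checks the size rules directly, without going
through the dummy-atom fragmentation route the library uses. It exists so
the fragmenter can be validated against a second, structurally different
path to the same answer.
"""

from __future__ import annotations

from random import Random

from rdkit import Chem

RING_POOL = [
    "c1ccccc1",
    "C1CCCCC1",
    "c1ccncc1",
    "C1CCNCC1",
    "c1ccc2ccccc2c1",
    "C1CCOC1",
    "c1cc[nH]c1",
    "c1ccsc1",
]
CHAIN_POOL = [
    "C",
    "N",
    "O",
    "CC",
    "CCC",
    "C(C)C",
    "Cl",
    "F",
    "CCO",
    "CC(=O)C",
    "CN",
    "C(F)(F)F",
]


def _heavy(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _attachable(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetTotalNumHs() >= 1 and a.GetNumExplicitHs() == 0 and a.GetAtomicNum() > 1
    ]


def random_molecule(rng: Random, max_heavy: int = 20) -> str:
    """A random small molecule assembled from ring systems and chains."""
    mol = Chem.MolFromSmiles(rng.choice(RING_POOL + CHAIN_POOL))
    for _ in range(rng.randint(0, 3)):
        piece = Chem.MolFromSmiles(rng.choice(CHAIN_POOL + RING_POOL[:4]))
        if _heavy(mol) + _heavy(piece) > max_heavy:
            break
        anchors = _attachable(mol)
        joints = _attachable(piece)
        if not anchors or not joints:
            continue
        n0 = mol.GetNumAtoms()
        combo = Chem.RWMol(Chem.CombineMols(mol, piece))
        combo.AddBond(rng.choice(anchors), n0 + rng.choice(joints), Chem.BondType.SINGLE)
        candidate = combo.GetMol()
        try:
            Chem.SanitizeMol(candidate)
        except Exception:
            continue
        mol = candidate
    return Chem.MolToSmiles(mol)


def bruteforce_fragmentations(
    smiles: str,
    core_ratio: float = 2.0,
    max_sub_atoms: int = 13,
) -> set[tuple[str, str, int, int, int]]:
    """Delete every acyclic single heavy-heavy bond; check rules directly.

    Returns tuples (core_smiles, substituent_smiles, position_class,
    sub_heavy, core_heavy), deduplicated.
    """
    mol = Chem.MolFromSmiles(smiles)
    results = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a1, a2 = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if mol.GetAtomWithIdx(a1).GetAtomicNum() <= 1:
            continue
        if mol.GetAtomWithIdx(a2).GetAtomicNum() <= 1:
            continue
        em = Chem.RWMol(mol)
        em.RemoveBond(a1, a2)
        cut = em.GetMol()
        Chem.SanitizeMol(cut)
        mapping: list[tuple[int, ...]] = []
        frags = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True,
                                 fragsMolAtomMapping=mapping)
        if len(frags) != 2:
            continue
        sizes = [_heavy(f) for f in frags]
        core_i = 0 if sizes[0] >= sizes[1] else 1
        core_heavy, sub_heavy = sizes[core_i], sizes[1 - core_i]
        if core_heavy < core_ratio * sub_heavy or sub_heavy > max_sub_atoms:
            continue
        # core: identify capped atom inside the fragment, classify by
        # canonical ranks computed directly on the fragment mol
        core_frag = Chem.Mol(frags[core_i])
        Chem.AssignStereochemistry(core_frag, cleanIt=True, force=True)
        cut_atom = a1 if a1 in mapping[core_i] else a2
        idx_in_frag = mapping[core_i].index(cut_atom)
        ranks = list(Chem.CanonicalRankAtoms(core_frag, breakTies=False))
        position_class = ranks[idx_in_frag]
        core_smiles = Chem.MolToSmiles(core_frag)
        # substituent: re-attach a dummy at the cut atom
        sub_frag = Chem.RWMol(frags[1 - core_i])
        sub_cut = a2 if cut_atom == a1 else a1
        sub_idx = mapping[1 - core_i].index(sub_cut)
        dummy = sub_frag.AddAtom(Chem.Atom(0))
        sub_frag.AddBond(sub_idx, dummy, Chem.BondType.SINGLE)
        sub_mol = sub_frag.GetMol()
        Chem.SanitizeMol(sub_mol)
        Chem.AssignStereochemistry(sub_mol, cleanIt=True, force=True)
        sub_smiles = Chem.MolToSmiles(sub_mol)
        results.add((core_smiles, sub_smiles, position_class, sub_heavy, core_heavy))
    return results


def reattach(core_smiles: str, position_class: int, sub_smiles: str) -> str:
    """Attach a dummy-labeled substituent at a class-representative atom.

    Used to verify that a decomposition reconstructs its parent molecule.
    """
    core = Chem.MolFromSmiles(core_smiles)
    ranks = list(Chem.CanonicalRankAtoms(core, breakTies=False))
    anchor = next(
        a.GetIdx()
        for a in core.GetAtoms()
        if ranks[a.GetIdx()] == position_class and a.GetTotalNumHs() >= 1
    )
    sub = Chem.MolFromSmiles(sub_smiles)
    n0 = core.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(core, sub))
    dummy = next(
        a.GetIdx() for a in combo.GetAtoms() if a.GetAtomicNum() == 0
    )
    joint = combo.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
    combo.RemoveAtom(dummy)
    if joint > dummy:
        joint -= 1
    if anchor > dummy:
        anchor -= 1
    combo.AddBond(anchor, joint, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)
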