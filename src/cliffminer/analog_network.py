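"""Analog sets and dual-site / isomer analog-pair enumeration.

Compounds active against the same target and sharing the same H-capped
core form an analog set. Within a set, every unordered pair whose
substituents sit at *different* symmetry classes of the core is an analog
pair differing at two substitution sites (each compound implicitly carries
H at the other's site):

* ``iso`` — the same substituent at two different sites: the two parents
  are constitutional isomers;
* ``ds``  — two different substituents at different sites, with the size
  difference between the exchanged substituents capped (default 8 heavy
  atoms).

A compound pair may qualify through several alternative cores; pairs are
therefore deduplicated per (target, compound, compound), keeping the
largest core as the representative decomposition and recording every
supporting core as evidence, so each pair is counted once downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .data_ingest import CompoundActivity
from .fragmenter import Fragmentation

ISO = "iso"
DS = "ds"


@dataclass(frozen=True, order=True)
class AnalogSetMember:
    compound_id: str
    substituent_smiles: str
    position_class: int
    pki: float
    sub_heavy_atoms: int


@dataclass(frozen=True)
class AnalogSet:
    """All decompositions onto one core among compounds sharing one target."""

    target_id: str
    core_smiles: str
    core_heavy_atoms: int
    members: tuple[AnalogSetMember, ...]

    def n_compounds(self) -> int:
        return len({m.compound_id for m in self.members})


@dataclass(frozen=True)
class AnalogPair:
    """Unordered pair of analogs substituted at two distinct core positions."""

    target_id: str
    core_smiles: str
    core_heavy_atoms: int
    a: AnalogSetMember
    b: AnalogSetMember
    pair_type: str
    size_diff: int
    evidence: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def key(self) -> tuple[str, str, str]:
        lo, hi = sorted((self.a.compound_id, self.b.compound_id))
        return (self.target_id, lo, hi)


def build_analog_sets(
    fragmentations: Iterable[Fragmentation],
    activities: Sequence[CompoundActivity],
) -> list[AnalogSet]:
    """Group decompositions into analog sets keyed by (target, core).

    Each fragmentation joins the set of every target its compound is active
    on, carrying that target's pKi. Sets with fewer than two distinct
    compounds cannot form pairs and are dropped.
    """
    targets_of: dict[str, list[CompoundActivity]] = {}
    for act in activities:
        targets_of.setdefault(act.compound_id, []).append(act)

    grouped: dict[tuple[str, str], dict[AnalogSetMember, None]] = {}
    core_sizes: dict[str, int] = {}
    for frag in fragmentations:
        for act in targets_of.get(frag.compound_id, ()):
            member = AnalogSetMember(
                compound_id=frag.compound_id,
                substituent_smiles=frag.substituent_smiles,
                position_class=frag.position_class,
                pki=act.pki,
                sub_heavy_atoms=frag.sub_heavy_atoms,
            )
            grouped.setdefault((act.target_id, frag.core_smiles), {})[member] = None
            core_sizes[frag.core_smiles] = frag.core_heavy_atoms

    sets = []
    for (target_id, core), members in sorted(grouped.items()):
        analog_set = AnalogSet(
            target_id=target_id,
            core_smiles=core,
            core_heavy_atoms=core_sizes[core],
            members=tuple(sorted(members)),
        )
        if analog_set.n_compounds() >= 2:
            sets.append(analog_set)
    return sets


def enumerate_pairs(analog_set: AnalogSet, max_size_diff: int = 8) -> list[AnalogPair]:
    """All qualifying two-site analog pairs within one set.

    Pairs require distinct compounds and distinct position classes; pairs
    at equal classes are classic single-site analogs and excluded. The
    exchanged substituents may differ by at most ``max_size_diff`` heavy
    atoms. Output is invariant to member ordering.
    """
    pairs = []
    for m1, m2 in combinations(analog_set.members, 2):
        if m1.compound_id == m2.compound_id:
            continue
        if m1.position_class == m2.position_class:
            continue
        size_diff = abs(m1.sub_heavy_atoms - m2.sub_heavy_atoms)
        if size_diff > max_size_diff:
            continue
        pair_type = ISO if m1.substituent_smiles == m2.substituent_smiles else DS
        a, b = sorted((m1, m2))
        pairs.append(
            AnalogPair(
                target_id=analog_set.target_id,
                core_smiles=analog_set.core_smiles,
                core_heavy_atoms=analog_set.core_heavy_atoms,
                a=a,
                b=b,
                pair_type=pair_type,
                size_diff=size_diff,
                evidence=((analog_set.core_smiles, pair_type),),
            )
        )
    return pairs


def dedupe_pairs(pairs: Iterable[AnalogPair]) -> list[AnalogPair]:
    """One pair per (target, compound, compound) across alternative cores.

    The retained record is the one with the largest core (ties broken by
    lexicographically smallest core SMILES) and is classified by that
    core's decomposition; all supporting (core, type) combinations are
    kept in the evidence field.
    """
    by_key: dict[tuple[str, str, str], list[AnalogPair]] = {}
    for pair in pairs:
        by_key.setdefault(pair.key(), []).append(pair)

    out = []
    for key in sorted(by_key):
        candidates = by_key[key]
        best = min(candidates, key=lambda p: (-p.core_heavy_atoms, p.core_smiles))
        evidence = tuple(
            sorted({ev for p in candidates for ev in p.evidence})
        )
        out.append(
            AnalogPair(
                target_id=best.target_id,
                core_smiles=best.core_smiles,
                core_heavy_atoms=best.core_heavy_atoms,
                a=best.a,
                b=best.b,
                pair_type=best.pair_type,
                size_diff=best.size_diff,
                evidence=evidence,
            )
        )
    return out
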