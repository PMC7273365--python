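"""Activity-cliff calling, category assignment and ds-cliff extension.

An analog pair becomes an activity cliff when its potency difference is
at least 100-fold (delta pKi >= 2, inclusive; ``min_fold`` configurable).
Every cliff found here differs at two substitution sites and is therefore
a dual-site cliff (``ds``); pairs carrying the same substituent at two
sites additionally get the ``iso`` category — isomer cliffs are a special
case of dual-site cliffs. Cliffs whose shared core contains a privileged
substructure get the ``ps`` category.

A ds cliff can be *extended* by searching its analog set for structural
isomers of its two compounds with the substituent moved to the respective
other site: up to two repositioned isomers (of the potent and of the weak
compound) yield a four-compound data structure that resolves how much
each substitution site contributes to cliff formation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from rdkit import Chem

from .analog_network import ISO, AnalogPair, AnalogSet, AnalogSetMember
from .data_ingest import CompoundActivity
from .errors import DataIntegrityError
from .ps_library import PrivilegedSubstructure, compile_pattern, pattern_heavy_atoms

#: Tolerance absorbing floating-point noise in pKi arithmetic at the
#: inclusive "at least 100-fold" boundary.
_DELTA_EPS = 1e-9

CAT_DS = "ds"
CAT_ISO = "iso"
CAT_PS = "ps"

FULL = "full"
PARTIAL = "partial"
NONE = "none"


@dataclass(frozen=True)
class ActivityCliff:
    pair: AnalogPair
    delta_pki: float
    highly_potent: str
    weakly_potent: str
    categories: frozenset[str]
    ps_smarts: str = ""
    ps_matches: tuple[str, ...] = ()


@dataclass(frozen=True)
class ExtendedDsCliff:
    """A ds cliff plus up to two repositioned-substituent isomers."""

    cliff: ActivityCliff
    iso_of_potent: AnalogSetMember | None
    iso_of_weak: AnalogSetMember | None
    extension_status: str


def call_cliffs(
    pairs: Iterable[AnalogPair],
    activities: Sequence[CompoundActivity],
    min_fold: float = 100.0,
) -> list[ActivityCliff]:
    """Keep pairs whose members differ by at least ``min_fold`` in potency.

    Raises :class:`DataIntegrityError` if a pair member has no potency on
    the pair's target.
    """
    import math

    pki_of = {(a.compound_id, a.target_id): a.pki for a in activities}
    threshold = math.log10(min_fold) - _DELTA_EPS

    cliffs = []
    for pair in pairs:
        for member in (pair.a, pair.b):
            if (member.compound_id, pair.target_id) not in pki_of:
                raise DataIntegrityError(
                    f"no potency for compound {member.compound_id!r} "
                    f"on target {pair.target_id!r}"
                )
        delta = abs(pair.a.pki - pair.b.pki)
        if delta < threshold:
            continue
        potent, weak = (
            (pair.a, pair.b) if pair.a.pki >= pair.b.pki else (pair.b, pair.a)
        )
        categories = {CAT_DS}
        if pair.pair_type == ISO:
            categories.add(CAT_ISO)
        cliffs.append(
            ActivityCliff(
                pair=pair,
                delta_pki=delta,
                highly_potent=potent.compound_id,
                weakly_potent=weak.compound_id,
                categories=frozenset(categories),
            )
        )
    return cliffs


def annotate_privileged(
    cliffs: Iterable[ActivityCliff],
    ps_library: Sequence[PrivilegedSubstructure],
    scope: str = "core",
    activities: Sequence[CompoundActivity] | None = None,
) -> list[ActivityCliff]:
    """Add the ``ps`` category to cliffs containing a privileged substructure.

    ``scope`` controls where patterns are matched:

    * ``core`` (default) — the shared capped core, guaranteeing the
      substructure is present in both cliff compounds;
    * ``either`` / ``both`` — the full molecules of at least one / both
      compounds (requires ``activities`` for the structures).

    All matching patterns are recorded; the reported pattern is the
    largest by heavy-atom count (ties broken by library order).
    """
    if scope not in {"core", "either", "both"}:
        raise ValueError(f"unknown PS match scope: {scope!r}")
    smiles_of: dict[str, str] = {}
    if scope != "core":
        if activities is None:
            raise ValueError(f"scope {scope!r} requires activities")
        smiles_of = {a.compound_id: a.canonical_smiles for a in activities}

    mol_cache: dict[str, Chem.Mol] = {}

    def _mol(smiles: str) -> Chem.Mol:
        if smiles not in mol_cache:
            mol_cache[smiles] = Chem.MolFromSmiles(smiles)
        return mol_cache[smiles]

    annotated = []
    for cliff in cliffs:
        if scope == "core":
            targets = [_mol(cliff.pair.core_smiles)]
            need = 1
        else:
            targets = [
                _mol(smiles_of[cliff.pair.a.compound_id]),
                _mol(smiles_of[cliff.pair.b.compound_id]),
            ]
            need = 1 if scope == "either" else 2
        matches = []
        for ps in ps_library:
            query = compile_pattern(ps.pattern)
            if sum(1 for t in targets if t.HasSubstructMatch(query)) >= need:
                matches.append(ps.pattern)
        if matches:
            reported = max(matches, key=lambda p: (pattern_heavy_atoms(p), -matches.index(p)))
            annotated.append(
                replace(
                    cliff,
                    categories=cliff.categories | {CAT_PS},
                    ps_smarts=reported,
                    ps_matches=tuple(matches),
                )
            )
        else:
            annotated.append(cliff)
    return annotated


def extend_ds_cliff(cliff: ActivityCliff, analog_set: AnalogSet) -> ExtendedDsCliff:
    """Search the cliff's analog set for the two repositioned isomers.

    The isomer of the potent compound carries the potent compound's
    substituent at the weak compound's position class; symmetrically for
    the weak compound. Isomers must be compounds distinct from both cliff
    members. Extension status is ``full`` (both found), ``partial``
    (exactly one) or ``none``.
    """
    pair = cliff.pair
    potent, weak = (
        (pair.a, pair.b) if pair.a.compound_id == cliff.highly_potent else (pair.b, pair.a)
    )
    excluded = {potent.compound_id, weak.compound_id}

    def _find(substituent: str, position_class: int) -> AnalogSetMember | None:
        hits = [
            m
            for m in analog_set.members
            if m.substituent_smiles == substituent
            and m.position_class == position_class
            and m.compound_id not in excluded
        ]
        return min(hits) if hits else None

    iso_of_potent = _find(potent.substituent_smiles, weak.position_class)
    iso_of_weak = _find(weak.substituent_smiles, potent.position_class)
    n_found = sum(x is not None for x in (iso_of_potent, iso_of_weak))
    status = {2: FULL, 1: PARTIAL, 0: NONE}[n_found]
    return ExtendedDsCliff(
        cliff=cliff,
        iso_of_potent=iso_of_potent,
        iso_of_weak=iso_of_weak,
        extension_status=status,
    )


def extend_all(
    cliffs: Iterable[ActivityCliff],
    analog_sets: Iterable[AnalogSet],
) -> list[ExtendedDsCliff]:
    """Extend every cliff against its own (target, core) analog set."""
    set_index: Mapping[tuple[str, str], AnalogSet] = {
        (s.target_id, s.core_smiles): s for s in analog_sets
    }
    out = []
    for cliff in cliffs:
        key = (cliff.pair.target_id, cliff.pair.core_smiles)
        analog_set = set_index.get(key)
        if analog_set is None:
            raise DataIntegrityError(f"no analog set for cliff on {key}")
        out.append(extend_ds_cliff(cliff, analog_set))
    return out
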