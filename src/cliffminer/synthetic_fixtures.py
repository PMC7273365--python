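"""Synthetic analog series with planted activity cliffs.

The generator emulates the situation the cliff search assumes in real
bioactivity data: small analog series sharing a scaffold ("core"), with
substituents placed at two topologically distinct scaffold positions and
Ki values assigned from a simple potency model (per-series baseline, a
planted potency offset for selected "potent" compounds, and sub-log-unit
noise). It emits a ChEMBL-shaped activity table in which every row passes
the high-confidence filters, alongside a ground-truth table of every
expected analog pair, cliff, category and extension status.

The truth table is computed by an independent brute-force enumerator over
the generated (scaffold, position, substituent, pKi) metadata — direct
rule checks over all compound pairs — never by the search pipeline, so
end-to-end tests are not circular. Molecules are built by literal string
assembly at template attachment markers, which is why the ground-truth
decomposition of every fixture compound is known by construction.

:func:`corrupt_fixture` injects rows that the ingest stage must filter or
standardize away (wrong relation, low confidence, foreign units, salt
forms) without changing the truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from random import Random
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .data_ingest import DEFAULT_COLUMNS
from .errors import FixtureSpecError
from .ps_library import PrivilegedSubstructure, compile_pattern

_CLIFF_DELTA = 2.0 - 1e-9  # inclusive 100-fold criterion, as in cliff calling

POSITIONS = ("a", "b")


@dataclass(frozen=True)
class CoreTemplate:
    """A scaffold SMILES template with two attachment markers ``{a}``/``{b}``.

    Markers must sit at topologically distinct positions of the bare
    scaffold; substituents are inserted as parenthesized branches.
    """

    name: str
    template: str

    def bare_smiles(self) -> str:
        return Chem.CanonSmiles(self.template.format(a="", b=""))

    def instantiate(self, position: str, substituent: str) -> str:
        if position not in POSITIONS:
            raise FixtureSpecError(f"unknown position {position!r}")
        subs = {"a": "", "b": ""}
        subs[position] = f"({substituent})"
        return Chem.CanonSmiles(self.template.format(**subs))

    def positions_distinct(self) -> bool:
        # probe identity test: equivalent positions make the two
        # mono-substituted probes the same molecule
        return self.instantiate("a", "C") != self.instantiate("b", "C")


#: Default scaffolds: one privileged core (quinoline) and one that is not.
DEFAULT_TEMPLATES = (
    CoreTemplate("naphthalene", "c1ccc2cc{b}ccc2c1{a}"),
    CoreTemplate("quinoline", "c1ccc2nc{b}ccc2c1{a}"),
)

#: Small substituents (1-3 heavy atoms), attached through their first atom.
DEFAULT_POOL = ("C", "CC", "CCC", "Cl", "F", "OC", "CO", "N")


@dataclass(frozen=True)
class SeriesSpec:
    """Explicit analog series: (position, substituent, pKi) members."""

    target_id: str
    template: CoreTemplate
    members: tuple[tuple[str, str, float], ...]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Random mode populates, for every (target, scaffold) combination,
    ``n_per_position`` substituents at each of the two positions (with one
    substituent shared between positions when ``include_iso`` is set) and
    raises ``n_potent`` randomly chosen compounds by ``cliff_offset`` pKi
    units. With the defaults (offset 3.0, noise 0.4) every potent/weak
    pair across positions is a planted cliff and no other pair comes near
    the 100-fold threshold. Alternatively, ``series`` fixes the members
    and potencies verbatim.
    """

    core_templates: tuple[CoreTemplate, ...] = DEFAULT_TEMPLATES
    substituent_pool: tuple[str, ...] = DEFAULT_POOL
    n_targets: int = 2
    n_per_position: int = 3
    n_potent: int = 1
    base_pki: float = 6.5
    cliff_offset: float = 3.0
    noise: float = 0.4
    include_iso: bool = True
    seed: int = 0
    series: tuple[SeriesSpec, ...] = ()

    def validate(self) -> None:
        if self.cliff_offset < 2.0:
            raise FixtureSpecError("planted cliff offset must be at least 2.0 pKi units")
        if not 0 <= self.noise < 0.5:
            raise FixtureSpecError("noise amplitude must lie in [0, 0.5)")
        if not self.series and self.n_per_position < 1:
            raise FixtureSpecError("need at least one substituent per position")
        templates = tuple(s.template for s in self.series) or self.core_templates
        for tpl in templates:
            if not tpl.positions_distinct():
                raise FixtureSpecError(
                    f"template {tpl.name!r} has equivalent attachment positions; "
                    "two distinct sites (and hence isomer cliffs) are impossible"
                )
        labeled = [Chem.CanonSmiles(f"[*]{s}") for s in self.substituent_pool]
        if len(set(labeled)) != len(labeled):
            raise FixtureSpecError("substituent pool contains equivalent fragments")
        max_sub = max(_heavy_atoms(s) for s in self.substituent_pool)
        for tpl in templates:
            core_heavy = _heavy_atoms(tpl.bare_smiles())
            if core_heavy < 2 * max_sub or max_sub > 13:
                raise FixtureSpecError(
                    f"scaffold {tpl.name!r} too small for the substituent pool"
                )


@dataclass(frozen=True)
class TruthCompound:
    compound_id: str
    target_id: str
    template: str
    position: str
    substituent: str
    smiles: str
    pki: float


@dataclass(frozen=True)
class TruthPair:
    target_id: str
    cpd_a: str
    cpd_b: str
    pair_type: str
    is_cliff: bool
    categories: tuple[str, ...] = ()
    extension_status: str = ""


@dataclass
class TruthTable:
    """Ground truth computed combinatorially from generation metadata."""

    compounds: list[TruthCompound]
    pairs: list[TruthPair]

    def cliffs(self) -> list[TruthPair]:
        return [p for p in self.pairs if p.is_cliff]

    def pair_keys(self) -> set[tuple[str, str, str, str]]:
        return {(p.target_id, p.cpd_a, p.cpd_b, p.pair_type) for p in self.pairs}

    def cliff_keys(self) -> set[tuple[str, str, str, tuple[str, ...], str]]:
        return {
            (p.target_id, p.cpd_a, p.cpd_b, p.categories, p.extension_status)
            for p in self.cliffs()
        }

    def summary(self) -> dict[str, int]:
        cliffs = self.cliffs()
        return {
            "n_compounds": len({c.smiles for c in self.compounds}),
            "n_targets": len({c.target_id for c in self.compounds}),
            "n_aps": len(self.pairs),
            "n_acs": len(cliffs),
            "n_iso_acs": sum("iso" in c.categories for c in cliffs),
            "n_ps_acs": sum("ps" in c.categories for c in cliffs),
            "n_ext_full": sum(c.extension_status == "full" for c in cliffs),
            "n_ext_partial": sum(c.extension_status == "partial" for c in cliffs),
            "n_ext_none": sum(c.extension_status == "none" for c in cliffs),
        }

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target_id": p.target_id,
                    "cpd_a": p.cpd_a,
                    "cpd_b": p.cpd_b,
                    "pair_type": p.pair_type,
                    "is_cliff": int(p.is_cliff),
                    "categories": ";".join(p.categories),
                    "extension_status": p.extension_status,
                }
                for p in self.pairs
            ]
        )


def _heavy_atoms(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FixtureSpecError(f"unparseable fixture fragment: {smiles!r}")
    return mol.GetNumHeavyAtoms()


def _build_series(spec: FixtureSpec, rng: Random) -> list[SeriesSpec]:
    if spec.series:
        return list(spec.series)
    series = []
    for t in range(1, spec.n_targets + 1):
        target_id = f"T-{t:02d}"
        for tpl in spec.core_templates:
            placements: list[tuple[str, str]] = []
            subs_a = rng.sample(spec.substituent_pool, spec.n_per_position)
            subs_b = rng.sample(spec.substituent_pool, spec.n_per_position)
            if spec.include_iso and subs_a[0] not in subs_b:
                subs_b[0] = subs_a[0]
            placements += [("a", s) for s in subs_a]
            placements += [("b", s) for s in subs_b]
            base = spec.base_pki + rng.uniform(-0.3, 0.3)
            pkis = [
                round(base + rng.uniform(-spec.noise, spec.noise), 3)
                for _ in placements
            ]
            for i in rng.sample(range(len(placements)), spec.n_potent):
                pkis[i] = round(pkis[i] + spec.cliff_offset, 3)
            series.append(
                SeriesSpec(
                    target_id=target_id,
                    template=tpl,
                    members=tuple(
                        (pos, sub, pki) for (pos, sub), pki in zip(placements, pkis)
                    ),
                )
            )
    return series


def _enumerate_truth(
    compounds: list[TruthCompound],
    ps_patterns: Sequence[PrivilegedSubstructure],
    template_by_name: dict[str, CoreTemplate],
    max_size_diff: int = 8,
) -> list[TruthPair]:
    """Brute-force expected pairs/cliffs from generation metadata alone."""
    scaffold_has_ps: dict[str, bool] = {}
    for name, tpl in template_by_name.items():
        scaffold = Chem.MolFromSmiles(tpl.bare_smiles())
        scaffold_has_ps[name] = any(
            scaffold.HasSubstructMatch(compile_pattern(ps.pattern)) for ps in ps_patterns
        )

    by_series: dict[tuple[str, str], list[TruthCompound]] = {}
    for c in compounds:
        by_series.setdefault((c.target_id, c.template), []).append(c)

    pairs: list[TruthPair] = []
    for (target_id, template), members in sorted(by_series.items()):
        for i, ci in enumerate(members):
            for cj in members[i + 1 :]:
                if ci.position == cj.position:
                    continue
                if abs(_heavy_atoms(ci.substituent) - _heavy_atoms(cj.substituent)) > max_size_diff:
                    continue
                pair_type = "iso" if ci.substituent == cj.substituent else "ds"
                is_cliff = abs(ci.pki - cj.pki) >= _CLIFF_DELTA
                categories: tuple[str, ...] = ()
                extension = ""
                if is_cliff:
                    cats = {"ds"}
                    if pair_type == "iso":
                        cats.add("iso")
                    if scaffold_has_ps[template]:
                        cats.add("ps")
                    categories = tuple(sorted(cats))
                    potent, weak = (ci, cj) if ci.pki >= cj.pki else (cj, ci)
                    taken = {ci.compound_id, cj.compound_id}
                    found_p = any(
                        m.substituent == potent.substituent
                        and m.position == weak.position
                        and m.compound_id not in taken
                        for m in members
                    )
                    found_w = any(
                        m.substituent == weak.substituent
                        and m.position == potent.position
                        and m.compound_id not in taken
                        for m in members
                    )
                    extension = {2: "full", 1: "partial", 0: "none"}[found_p + found_w]
                a, b = sorted((ci.compound_id, cj.compound_id))
                pairs.append(
                    TruthPair(target_id, a, b, pair_type, is_cliff, categories, extension)
                )
    return pairs


def generate_fixture(
    spec: FixtureSpec,
    ps_patterns: Sequence[PrivilegedSubstructure] = (),
) -> tuple[pd.DataFrame, TruthTable]:
    """Build the activity table and its independent ground truth.

    ``ps_patterns`` is the privileged-substructure library the downstream
    analysis will use; the truth table's ``ps`` flags are computed against
    it directly on the bare scaffolds.
    """
    spec.validate()
    rng = Random(spec.seed)
    series = _build_series(spec, rng)

    id_of: dict[str, str] = {}
    compounds: list[TruthCompound] = []
    seen_structures: dict[tuple[str, str], None] = {}
    template_by_name: dict[str, CoreTemplate] = {}
    for s in series:
        template_by_name[s.template.name] = s.template
        for position, substituent, pki in s.members:
            smiles = s.template.instantiate(position, substituent)
            if (s.target_id, smiles) in seen_structures:
                continue
            seen_structures[(s.target_id, smiles)] = None
            if smiles not in id_of:
                id_of[smiles] = f"CPD-{len(id_of) + 1:04d}"
            compounds.append(
                TruthCompound(
                    compound_id=id_of[smiles],
                    target_id=s.target_id,
                    template=s.template.name,
                    position=position,
                    substituent=substituent,
                    smiles=smiles,
                    pki=pki,
                )
            )

    rows = []
    for c in compounds:
        ki_nm = 10.0 ** (9.0 - c.pki)
        rows.append(
            {
                DEFAULT_COLUMNS["compound_id"]: c.compound_id,
                DEFAULT_COLUMNS["smiles"]: c.smiles,
                DEFAULT_COLUMNS["target_id"]: c.target_id,
                DEFAULT_COLUMNS["organism"]: "Homo sapiens",
                DEFAULT_COLUMNS["assay_relationship_type"]: "D",
                DEFAULT_COLUMNS["assay_confidence_score"]: 9,
                DEFAULT_COLUMNS["measurement_type"]: "Ki",
                DEFAULT_COLUMNS["relation"]: "=",
                DEFAULT_COLUMNS["value"]: f"{ki_nm:.8g}",
                DEFAULT_COLUMNS["units"]: "nM",
            }
        )
    table = pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values()))
    truth = TruthTable(
        compounds=compounds,
        pairs=_enumerate_truth(compounds, ps_patterns, template_by_name),
    )
    return table, truth


CORRUPTION_MODES = ("bad-units", "relation-gt", "low-confidence", "salt-forms")


def corrupt_fixture(
    table: pd.DataFrame,
    modes: Iterable[str] = CORRUPTION_MODES,
    seed: int = 0,
) -> pd.DataFrame:
    """Inject rows the pipeline must discard; the ground truth is unchanged.

    ``bad-units`` rows carry non-molar units, ``relation-gt`` a ``>``
    qualifier, ``low-confidence`` a confidence score of 8, and
    ``salt-forms`` duplicate existing measurements as hydrochloride salts
    (which standardize back to the parent structure). Injected rows are
    shuffled into the table at random positions.
    """
    rng = Random(seed)
    modes = list(modes)
    unknown = set(modes) - set(CORRUPTION_MODES)
    if unknown:
        raise FixtureSpecError(f"unknown corruption modes: {sorted(unknown)}")
    extra: list[dict] = []
    donors = table.to_dict("records")
    for mode in modes:
        for row in rng.sample(donors, min(3, len(donors))):
            row = dict(row)
            if mode == "bad-units":
                row[DEFAULT_COLUMNS["units"]] = "ug.mL-1"
            elif mode == "relation-gt":
                row[DEFAULT_COLUMNS["relation"]] = ">"
                row[DEFAULT_COLUMNS["value"]] = "10000"
            elif mode == "low-confidence":
                row[DEFAULT_COLUMNS["assay_confidence_score"]] = 8
                row[DEFAULT_COLUMNS["value"]] = "3.14"
            elif mode == "salt-forms":
                row[DEFAULT_COLUMNS["smiles"]] = row[DEFAULT_COLUMNS["smiles"]] + ".Cl"
            extra.append(row)
    combined = donors + extra
    rng.shuffle(combined)
    return pd.DataFrame(combined, columns=table.columns)
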