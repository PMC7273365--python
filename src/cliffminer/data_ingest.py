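"""Reading, filtering and standardizing compound-activity tables.

The entry point of a cliff search is a flat activity table (one row per
assay measurement). This module turns such a table into a clean list of
per-(compound, target) potencies:

1. :func:`load_activity_table` parses the table under a configurable
   column mapping and separates unusable rows into a rejects list.
2. :func:`filter_high_confidence` keeps only direct-binding (relationship
   type ``D``), top-confidence (score 9), human-target Ki measurements
   with an exact ``=`` relation — the high-confidence slice on which
   equilibrium constants are comparable across assays.
3. :func:`standardize_structure` strips salts/solvents, neutralizes
   charges and canonicalizes the SMILES.
4. :func:`aggregate_potency` converts each Ki to pKi = -log10(Ki [M]) and
   averages replicate measurements per (structure, target), discarding
   compounds whose replicates disagree by more than a configurable pKi
   spread (default 1 log unit) so that 100-fold cliffs cannot be
   measurement artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import ConfigurationError, StructureError, UnitError

RDLogger.DisableLog("rdApp.*")

#: Default column mapping; keys are record fields, values are the column
#: headers of a ChEMBL activity export.
DEFAULT_COLUMNS: dict[str, str] = {
    "compound_id": "molecule_chembl_id",
    "smiles": "canonical_smiles",
    "target_id": "target_chembl_id",
    "organism": "target_organism",
    "assay_relationship_type": "relationship_type",
    "assay_confidence_score": "confidence_score",
    "measurement_type": "standard_type",
    "relation": "standard_relation",
    "value": "standard_value",
    "units": "standard_units",
}

#: Units accepted for Ki values, with conversion factors to mol/L.
_UNIT_FACTORS = {"m": 1.0, "um": 1e-6, "µm": 1e-6, "μm": 1e-6, "nm": 1e-9}


@dataclass(frozen=True)
class ActivityRecord:
    """One raw assay measurement, prior to any filtering."""

    compound_id: str
    smiles: str
    target_id: str
    organism: str
    assay_relationship_type: str
    assay_confidence_score: int
    measurement_type: str
    relation: str
    value: float
    units: str


@dataclass(frozen=True)
class RejectedRow:
    """A table row that could not be turned into an :class:`ActivityRecord`."""

    row_number: int
    reason: str
    compound_id: str = ""


@dataclass(frozen=True)
class CompoundActivity:
    """A standardized compound with one aggregated pKi on one target."""

    compound_id: str
    canonical_smiles: str
    target_id: str
    pki: float
    n_measurements: int = 1
    pki_range: float = 0.0


def load_activity_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[ActivityRecord], list[RejectedRow]]:
    """Read a TSV/CSV activity table into records plus a rejects list.

    ``dialect`` maps record fields to column headers; unspecified fields
    fall back to :data:`DEFAULT_COLUMNS`. Extra, unmapped columns are
    ignored. Rows whose potency value does not parse as a positive number,
    or whose SMILES is empty, go to the rejects list with a reason.
    """
    columns = dict(DEFAULT_COLUMNS)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown dialect fields: {sorted(unknown)}")
        columns.update(dialect)

    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return [], []

    missing = [c for c in columns.values() if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"mapped columns absent from {path.name}: {missing}")

    records: list[ActivityRecord] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        raw = dict(zip(frame.columns, row))
        cid = raw[columns["compound_id"]].strip()
        smiles = raw[columns["smiles"]].strip()
        if not smiles:
            rejects.append(RejectedRow(i, "empty SMILES", cid))
            continue
        try:
            value = float(raw[columns["value"]])
        except ValueError:
            rejects.append(RejectedRow(i, "unparseable value", cid))
            continue
        if not math.isfinite(value) or value <= 0:
            rejects.append(RejectedRow(i, "nonpositive value", cid))
            continue
        try:
            score = int(float(raw[columns["assay_confidence_score"]]))
        except ValueError:
            rejects.append(RejectedRow(i, "unparseable confidence score", cid))
            continue
        records.append(
            ActivityRecord(
                compound_id=cid,
                smiles=smiles,
                target_id=raw[columns["target_id"]].strip(),
                organism=raw[columns["organism"]].strip(),
                assay_relationship_type=raw[columns["assay_relationship_type"]].strip(),
                assay_confidence_score=score,
                measurement_type=raw[columns["measurement_type"]].strip(),
                relation=raw[columns["relation"]].strip(),
                value=value,
                units=raw[columns["units"]].strip(),
            )
        )
    return records, rejects


def filter_high_confidence(
    records: Iterable[ActivityRecord],
    organism: str = "Homo sapiens",
) -> list[ActivityRecord]:
    """Keep direct (type ``D``), confidence-9, exact Ki measurements on ``organism``.

    Pure, order-preserving and idempotent.
    """
    return [
        r
        for r in records
        if r.organism == organism
        and r.assay_relationship_type == "D"
        and r.assay_confidence_score == 9
        and r.measurement_type == "Ki"
        and r.relation == "="
    ]


_fragment_chooser = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()


def standardize_structure(smiles: str) -> str:
    """Return the canonical SMILES of the neutralized largest organic component.

    Deterministic; re-standardizing the output is a fixed point.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    mol = _fragment_chooser.choose(mol)
    mol = _uncharger.uncharge(mol)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _to_molar(value: float, units: str) -> float:
    factor = _UNIT_FACTORS.get(units.strip().lower())
    if factor is None:
        raise UnitError(units)
    return value * factor


def aggregate_potency(
    records: Sequence[ActivityRecord],
    max_pki_spread: float = 1.0,
    skip_unknown_units: bool = False,
) -> list[CompoundActivity]:
    """Aggregate filtered records into one pKi per (structure, target).

    Each Ki is converted to molar and to pKi = -log10(Ki). Measurements are
    grouped by standardized structure and target; structures recorded under
    several compound identifiers collapse to the lexicographically smallest
    identifier. Groups whose pKi spread exceeds ``max_pki_spread`` are
    discarded as irreproducible. Unknown units raise :class:`UnitError`
    unless ``skip_unknown_units`` is set, in which case those records are
    silently dropped.
    """
    groups: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for rec in records:
        try:
            ki_molar = _to_molar(rec.value, rec.units)
        except UnitError:
            if skip_unknown_units:
                continue
            raise
        canonical = standardize_structure(rec.smiles)
        pki = -math.log10(ki_molar)
        groups.setdefault((canonical, rec.target_id), []).append((rec.compound_id, pki))

    out: list[CompoundActivity] = []
    for (canonical, target_id), entries in groups.items():
        pkis = [p for _, p in entries]
        spread = max(pkis) - min(pkis)
        if spread > max_pki_spread:
            continue
        out.append(
            CompoundActivity(
                compound_id=min(cid for cid, _ in entries),
                canonical_smiles=canonical,
                target_id=target_id,
                pki=sum(pkis) / len(pkis),
                n_measurements=len(pkis),
                pki_range=spread,
            )
        )
    out.sort(key=lambda a: (a.target_id, a.compound_id))
    return out
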