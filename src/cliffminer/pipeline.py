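"""End-to-end pipeline and the deposition-style cliff-table writer.

``run_pipeline`` chains the stages — ingest, high-confidence filtering,
potency aggregation, fragmentation, analog-pair enumeration, cliff
calling, privileged-substructure annotation and ds-cliff extension — and
returns every intermediate plus a flat summary of per-stage counts.
``write_cliff_table`` serializes the result as a deterministic TSV, one
row per cliff, with category memberships, both compounds' identifiers,
SMILES and potencies, the shared core decomposition, the matched
privileged substructure (if any) and the extension isomers.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import analog_network, cliff_caller, data_ingest, fragmenter, ps_library
from .analog_network import AnalogPair, AnalogSet
from .cliff_caller import ExtendedDsCliff
from .data_ingest import ActivityRecord, CompoundActivity, RejectedRow
from .errors import CliffMinerError
from .fragmenter import Fragmentation

CLIFF_TABLE_COLUMNS = [
    "ac_id",
    "target_id",
    "categories",
    "cpd1_id",
    "cpd1_smiles",
    "cpd1_pki",
    "cpd2_id",
    "cpd2_smiles",
    "cpd2_pki",
    "delta_pki",
    "core_smiles",
    "sub1_smiles",
    "pos1_class",
    "sub2_smiles",
    "pos2_class",
    "ps_smiles",
    "extension_status",
    "iso_of_potent_id",
    "iso_of_weak_id",
]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds and I/O settings.

    Defaults are the criteria of the unified cliff search: 100-fold
    potency difference, substituents of at most 13 heavy atoms, a core at
    least twice the substituent's size, at most 8 heavy atoms size
    difference between exchanged substituents, privileged substructures
    screened at 100 unique compounds, and replicate potencies accepted up
    to a 1 log-unit spread.
    """

    activities_path: str | Path | None = None
    ps_library_path: str | Path | None = None
    column_map: Mapping[str, str] | None = None
    organism: str = "Homo sapiens"
    min_fold: float = 100.0
    max_sub_atoms: int = 13
    core_ratio: float = 2.0
    max_size_diff: int = 8
    ps_min_count: int = 100
    pki_spread_max: float = 1.0
    ps_scope: str = "core"
    out_dir: str | Path = "."
    seed: int = 0

    def __post_init__(self):
        for name in ("min_fold", "max_sub_atoms", "core_ratio", "max_size_diff",
                     "ps_min_count", "pki_spread_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class PipelineResult:
    records: list[ActivityRecord]
    rejects: list[RejectedRow]
    filtered: list[ActivityRecord]
    activities: list[CompoundActivity]
    fragmentations: list[Fragmentation]
    analog_sets: list[AnalogSet]
    pairs: list[AnalogPair]
    cliffs: list[ExtendedDsCliff]
    summary: dict[str, int] = field(default_factory=dict)


def _log(stage: str, message: str, verbose: bool) -> None:
    if verbose:
        print(f"[cliffminer] {stage}: {message}", file=sys.stderr)


def run_pipeline(
    config: RunConfig,
    records: Sequence[ActivityRecord] | None = None,
    ps_patterns: Sequence[ps_library.PrivilegedSubstructure] | None = None,
    verbose: bool = False,
) -> PipelineResult:
    """Execute the full search. Records may be passed in-memory or loaded
    from ``config.activities_path``; likewise the PS library (defaulting
    to the packaged starter set)."""
    rejects: list[RejectedRow] = []
    if records is None:
        if config.activities_path is None:
            raise CliffMinerError("no activity records and no activities_path")
        records, rejects = data_ingest.load_activity_table(
            config.activities_path, config.column_map
        )
    else:
        records = list(records)
    _log("ingest", f"{len(records)} records, {len(rejects)} rejects", verbose)

    if ps_patterns is None:
        path = config.ps_library_path or ps_library.starter_library_path()
        ps_patterns = ps_library.load_ps_definitions(path)

    filtered = data_ingest.filter_high_confidence(records, organism=config.organism)
    activities = data_ingest.aggregate_potency(
        filtered, max_pki_spread=config.pki_spread_max, skip_unknown_units=True
    )
    _log("filter", f"{len(filtered)} high-confidence records -> "
         f"{len(activities)} compound-target potencies", verbose)

    fragmentations: list[Fragmentation] = []
    for smiles in sorted({a.canonical_smiles for a in activities}):
        cid = min(a.compound_id for a in activities if a.canonical_smiles == smiles)
        fragmentations.extend(
            fragmenter.fragment_compound(
                smiles, cid, core_ratio=config.core_ratio,
                max_sub_atoms=config.max_sub_atoms,
            )
        )
    _log("fragment", f"{len(fragmentations)} decompositions", verbose)

    analog_sets = analog_network.build_analog_sets(fragmentations, activities)
    raw_pairs: list[AnalogPair] = []
    for s in analog_sets:
        raw_pairs.extend(analog_network.enumerate_pairs(s, config.max_size_diff))
    pairs = analog_network.dedupe_pairs(raw_pairs)
    _log("pairs", f"{len(analog_sets)} analog sets, {len(pairs)} analog pairs", verbose)

    called = cliff_caller.call_cliffs(pairs, activities, min_fold=config.min_fold)
    called = cliff_caller.annotate_privileged(
        called, ps_patterns, scope=config.ps_scope, activities=activities
    )
    extended = cliff_caller.extend_all(called, analog_sets)
    extended.sort(key=lambda e: (e.cliff.pair.target_id, e.cliff.pair.key()))
    _log("cliffs", f"{len(extended)} activity cliffs", verbose)

    result = PipelineResult(
        records=list(records),
        rejects=rejects,
        filtered=filtered,
        activities=activities,
        fragmentations=fragmentations,
        analog_sets=analog_sets,
        pairs=pairs,
        cliffs=extended,
    )
    result.summary = summarize(result)
    return result


def summarize(result: PipelineResult) -> dict[str, int]:
    """Per-stage counts, with the additive category identities.

    Isomer cliffs are a subset of dual-site cliffs, so totals decompose
    additively as iso + non-iso-ds within both the PS and non-PS groups.
    """
    cliffs = [e.cliff for e in result.cliffs]
    is_iso = [("iso" in c.categories) for c in cliffs]
    is_ps = [("ps" in c.categories) for c in cliffs]
    n = len(cliffs)
    n_iso = sum(is_iso)
    n_ps = sum(is_ps)
    n_ps_iso = sum(i and p for i, p in zip(is_iso, is_ps))
    return {
        "n_input_records": len(result.records),
        "n_rejected_rows": len(result.rejects),
        "n_high_confidence_records": len(result.filtered),
        "n_compounds": len({a.canonical_smiles for a in result.activities}),
        "n_targets": len({a.target_id for a in result.activities}),
        "n_analog_sets": len(result.analog_sets),
        "n_aps": len(result.pairs),
        "n_acs": n,
        "n_ds_acs": n,  # every cliff differs at two sites
        "n_iso_acs": n_iso,
        "n_noniso_ds_acs": n - n_iso,
        "n_ps_acs": n_ps,
        "n_nonps_acs": n - n_ps,
        "n_ps_iso_acs": n_ps_iso,
        "n_ps_noniso_ds_acs": n_ps - n_ps_iso,
        "n_nonps_iso_acs": n_iso - n_ps_iso,
        "n_nonps_noniso_ds_acs": (n - n_ps) - (n_iso - n_ps_iso),
        "n_ext_full": sum(e.extension_status == "full" for e in result.cliffs),
        "n_ext_partial": sum(e.extension_status == "partial" for e in result.cliffs),
        "n_ext_none": sum(e.extension_status == "none" for e in result.cliffs),
    }


def cliff_table_frame(
    cliffs: Sequence[ExtendedDsCliff],
    activities: Sequence[CompoundActivity],
) -> pd.DataFrame:
    """Deposition table as a DataFrame: sorted, one row per cliff.

    Compound 1 is the highly potent partner. pKi values are printed with
    two decimals; empty fields are empty strings.
    """
    smiles_of = {(a.compound_id, a.target_id): a.canonical_smiles for a in activities}
    ordered = sorted(cliffs, key=lambda e: (e.cliff.pair.target_id, e.cliff.pair.key()))
    rows = []
    for i, ext in enumerate(ordered, start=1):
        cliff = ext.cliff
        pair = cliff.pair
        potent, weak = (
            (pair.a, pair.b) if pair.a.compound_id == cliff.highly_potent else (pair.b, pair.a)
        )
        rows.append(
            {
                "ac_id": f"AC{i:06d}",
                "target_id": pair.target_id,
                "categories": ";".join(sorted(cliff.categories)),
                "cpd1_id": potent.compound_id,
                "cpd1_smiles": smiles_of[(potent.compound_id, pair.target_id)],
                "cpd1_pki": f"{potent.pki:.2f}",
                "cpd2_id": weak.compound_id,
                "cpd2_smiles": smiles_of[(weak.compound_id, pair.target_id)],
                "cpd2_pki": f"{weak.pki:.2f}",
                "delta_pki": f"{cliff.delta_pki:.2f}",
                "core_smiles": pair.core_smiles,
                "sub1_smiles": potent.substituent_smiles,
                "pos1_class": potent.position_class,
                "sub2_smiles": weak.substituent_smiles,
                "pos2_class": weak.position_class,
                "ps_smiles": cliff.ps_smarts,
                "extension_status": ext.extension_status,
                "iso_of_potent_id": ext.iso_of_potent.compound_id if ext.iso_of_potent else "",
                "iso_of_weak_id": ext.iso_of_weak.compound_id if ext.iso_of_weak else "",
            }
        )
    return pd.DataFrame(rows, columns=CLIFF_TABLE_COLUMNS)


def write_cliff_table(
    cliffs: Sequence[ExtendedDsCliff],
    activities: Sequence[CompoundActivity],
    path: str | Path,
) -> None:
    frame = cliff_table_frame(cliffs, activities)
    frame.to_csv(path, sep="\t", index=False)


def read_cliff_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_summary(summary: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as handle:
        for key, value in summary.items():
            handle.write(f"{key}={value}\n")


def write_rejects(rejects: Sequence[RejectedRow], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.row_number, r.compound_id, r.reason) for r in rejects],
        columns=["row_number", "compound_id", "reason"],
    )
    frame.to_csv(path, sep="\t", index=False)
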