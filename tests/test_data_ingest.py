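import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cliffminer.data_ingest import (
    ActivityRecord,
    aggregate_potency,
    filter_high_confidence,
    load_activity_table,
    standardize_structure,
)
from cliffminer.errors import ConfigurationError, StructureError, UnitError

HEADER = (
    "molecule_chembl_id\tcanonical_smiles\ttarget_chembl_id\ttarget_organism\t"
    "relationship_type\tconfidence_score\tstandard_type\tstandard_relation\t"
    "standard_value\tstandard_units"
)


def _row(cid="C1", smiles="CCO", target="T1", organism="Homo sapiens",
         rel_type="D", score="9", mtype="Ki", relation="=", value="50", units="nM"):
    return "\t".join([cid, smiles, target, organism, rel_type, score, mtype,
                      relation, value, units])


def _record(**kw):
    defaults = dict(
        compound_id="C1", smiles="CCO", target_id="T1", organism="Homo sapiens",
        assay_relationship_type="D", assay_confidence_score=9,
        measurement_type="Ki", relation="=", value=50.0, units="nM",
    )
    defaults.update(kw)
    return ActivityRecord(**defaults)


class TestLoadActivityTable:
    def test_well_formed_rows_parse_without_rejects(self, tmp_path):
        path = tmp_path / "act.tsv"
        path.write_text("\n".join([HEADER, _row("C1"), _row("C2"), _row("C3")]) + "\n")
        records, rejects = load_activity_table(path)
        assert len(records) == 3 and not rejects
        assert records[0].value == 50.0 and records[0].compound_id == "C1"

    def test_unparseable_value_is_rejected_with_reason(self, tmp_path):
        path = tmp_path / "act.tsv"
        path.write_text("\n".join([HEADER, _row("C1"), _row("C2", value="n/a"),
                                   _row("C3")]) + "\n")
        records, rejects = load_activity_table(path)
        assert len(records) == 2
        assert len(rejects) == 1
        assert rejects[0].reason == "unparseable value"
        assert rejects[0].compound_id == "C2"

    def test_empty_smiles_is_rejected(self, tmp_path):
        path = tmp_path / "act.tsv"
        path.write_text("\n".join([HEADER, _row(smiles="")]) + "\n")
        records, rejects = load_activity_table(path)
        assert not records and rejects[0].reason == "empty SMILES"

    def test_extra_unmapped_columns_are_ignored(self, tmp_path):
        path = tmp_path / "act.tsv"
        path.write_text(HEADER + "\textra_col\n" + _row() + "\tjunk\n")
        records, rejects = load_activity_table(path)
        assert len(records) == 1 and not rejects

    def test_missing_mapped_column_is_a_configuration_error(self, tmp_path):
        path = tmp_path / "act.tsv"
        path.write_text("only_one_column\nfoo\n")
        with pytest.raises(ConfigurationError):
            load_activity_table(path)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "act.tsv"
        path.write_text("")
        assert load_activity_table(path) == ([], [])

    def test_custom_dialect_remaps_columns(self, tmp_path):
        path = tmp_path / "act.csv"
        path.write_text(
            "id,smi,target_chembl_id,target_organism,relationship_type,"
            "confidence_score,standard_type,standard_relation,standard_value,"
            "standard_units\nC9,CCO,T1,Homo sapiens,D,9,Ki,=,50,nM\n"
        )
        records, _ = load_activity_table(
            path, dialect={"compound_id": "id", "smiles": "smi"}
        )
        assert records[0].compound_id == "C9"


class TestHighConfidenceFilter:
    def test_keeps_direct_confidence9_exact_human_ki(self):
        assert filter_high_confidence([_record()]) == [_record()]

    @pytest.mark.parametrize(
        "change",
        [
            {"relation": ">"},
            {"assay_confidence_score": 8},
            {"assay_relationship_type": "H"},
            {"organism": "Rattus norvegicus"},
            {"measurement_type": "IC50"},
        ],
    )
    def test_drops_any_violation(self, change):
        assert filter_high_confidence([_record(**change)]) == []

    @given(st.lists(st.sampled_from([
        _record(), _record(relation=">"), _record(assay_confidence_score=8),
        _record(measurement_type="IC50"), _record(organism="Mus musculus"),
    ]), max_size=30))
    def test_idempotent_and_order_preserving(self, records):
        once = filter_high_confidence(records)
        assert filter_high_confidence(once) == once
        assert once == [r for r in records if r in once]


class TestStandardize:
    def test_canonicalization_is_a_fixed_point(self):
        canonical = standardize_structure("C1=CC=CC=C1")
        assert standardize_structure(canonical) == canonical

    def test_salt_component_is_stripped(self):
        assert standardize_structure("CCO.Cl") == standardize_structure("CCO")

    def test_charges_are_neutralized(self):
        assert standardize_structure("CC[O-].[Na+]") == standardize_structure("CCO")

    def test_unparseable_smiles_raises_structure_error(self):
        with pytest.raises(StructureError) as err:
            standardize_structure("C1CC")
        assert "C1CC" in str(err.value)


class TestAggregatePotency:
    def test_one_nanomolar_is_pki_nine(self):
        (act,) = aggregate_potency([_record(value=1.0)])
        assert act.pki == pytest.approx(9.0, abs=1e-9)

    def test_replicates_within_one_log_are_averaged(self):
        (act,) = aggregate_potency([_record(value=10.0), _record(value=100.0)])
        assert act.pki == pytest.approx(7.5)
        assert act.pki_range == pytest.approx(1.0)
        assert act.n_measurements == 2

    def test_replicates_spanning_more_than_one_log_are_discarded(self):
        assert aggregate_potency([_record(value=1.0), _record(value=1000.0)]) == []

    def test_micromolar_and_molar_units_convert(self):
        (a,) = aggregate_potency([_record(value=1.0, units="uM")])
        assert a.pki == pytest.approx(6.0)
        (b,) = aggregate_potency([_record(value=1e-9, units="M")])
        assert b.pki == pytest.approx(9.0)

    def test_unknown_units_raise_unless_skipped(self):
        with pytest.raises(UnitError):
            aggregate_potency([_record(units="mg/mL")])
        assert aggregate_potency([_record(units="mg/mL")], skip_unknown_units=True) == []

    def test_same_structure_under_two_ids_merges_to_smallest_id(self):
        acts = aggregate_potency([
            _record(compound_id="C2", smiles="OCC"),
            _record(compound_id="C1", smiles="CCO"),
        ])
        assert len(acts) == 1 and acts[0].compound_id == "C1"

    @given(st.permutations([
        _record(value=10.0), _record(value=20.0),
        _record(compound_id="C2", smiles="CCN", value=5.0),
        _record(target_id="T2", value=400.0),
    ]))
    def test_permutation_invariant(self, records):
        baseline = aggregate_potency([
            _record(value=10.0), _record(value=20.0),
            _record(compound_id="C2", smiles="CCN", value=5.0),
            _record(target_id="T2", value=400.0),
        ])
        assert aggregate_potency(list(records)) == baseline

    def test_pki_matches_definition_to_1e9(self):
        (act,) = aggregate_potency([_record(value=37.0)])
        assert act.pki == pytest.approx(-math.log10(37.0e-9), abs=1e-9)
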