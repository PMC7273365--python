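import pytest

from cliffminer.analog_network import AnalogPair, AnalogSet, AnalogSetMember
from cliffminer.cliff_caller import (
    annotate_privileged,
    call_cliffs,
    extend_ds_cliff,
    extend_all,
)
from cliffminer.data_ingest import CompoundActivity
from cliffminer.errors import DataIntegrityError
from cliffminer.ps_library import PrivilegedSubstructure

CORE = "c1ccc2ccccc2c1"


def member(cid, sub, cls, pki, heavy=1):
    return AnalogSetMember(cid, sub, cls, pki, heavy)


def make_pair(pki_a, pki_b, pair_type="ds", core=CORE, target="T1"):
    a = member("C1", "*C", 0, pki_a)
    b = member("C2", "*C" if pair_type == "iso" else "*Cl", 4, pki_b)
    return AnalogPair(target, core, 10, a, b, pair_type, 0,
                      evidence=((core, pair_type),))


def activities_for(pair):
    return [
        CompoundActivity(m.compound_id, "Cc1cccc2ccccc12", pair.target_id, m.pki)
        for m in (pair.a, pair.b)
    ]


class TestCallCliffs:
    @pytest.mark.parametrize(
        "pki_a, pki_b, is_cliff",
        [
            (9.1, 5.0, True),
            (7.99, 6.0, False),  # delta 1.99 just below 100-fold
            (8.0, 6.0, True),    # delta exactly 2.0: "at least" is inclusive
        ],
    )
    def test_hundredfold_threshold(self, pki_a, pki_b, is_cliff):
        pair = make_pair(pki_a, pki_b)
        cliffs = call_cliffs([pair], activities_for(pair))
        assert bool(cliffs) is is_cliff
        if cliffs:
            assert cliffs[0].delta_pki == pytest.approx(abs(pki_a - pki_b))
            assert cliffs[0].highly_potent == "C1"

    def test_iso_pairs_carry_both_iso_and_ds_categories(self):
        pair = make_pair(9.0, 5.0, pair_type="iso")
        (cliff,) = call_cliffs([pair], activities_for(pair))
        assert cliff.categories == frozenset({"ds", "iso"})

    def test_ds_category_is_always_present(self):
        pair = make_pair(9.0, 5.0)
        (cliff,) = call_cliffs([pair], activities_for(pair))
        assert "ds" in cliff.categories

    def test_missing_potency_names_the_compound(self):
        pair = make_pair(9.0, 5.0)
        with pytest.raises(DataIntegrityError, match="C2"):
            call_cliffs([pair], activities_for(pair)[:1])

    def test_lowering_the_fold_threshold_grows_a_superset(self):
        pairs = [make_pair(9.0, 5.0), make_pair(7.5, 6.9, target="T2")]
        acts = activities_for(pairs[0]) + activities_for(pairs[1])
        strict = {c.pair.key() for c in call_cliffs(pairs, acts, min_fold=100)}
        loose = {c.pair.key() for c in call_cliffs(pairs, acts, min_fold=1)}
        assert strict <= loose and len(loose) == 2


INDOLE = PrivilegedSubstructure("indole", "c1ccc2[nH]ccc2c1")
QUINOLINE = PrivilegedSubstructure("quinoline", "c1ccc2ncccc2c1")


class TestAnnotatePrivileged:
    def _cliff(self, core):
        pair = make_pair(9.0, 5.0, core=core)
        return call_cliffs([pair], activities_for(pair))[0]

    def test_core_containing_pattern_gains_ps_category(self):
        cliff = self._cliff("c1ccc2ncccc2c1")
        (annotated,) = annotate_privileged([cliff], [INDOLE, QUINOLINE])
        assert "ps" in annotated.categories
        assert annotated.ps_smarts == QUINOLINE.pattern

    def test_nonmatching_core_is_unchanged(self):
        cliff = self._cliff(CORE)  # naphthalene contains no library pattern
        (annotated,) = annotate_privileged([cliff], [INDOLE, QUINOLINE])
        assert "ps" not in annotated.categories and annotated.ps_smarts == ""

    def test_pattern_only_in_substituent_does_not_count_under_core_scope(self):
        # the substituent string is never matched in core scope
        pair = make_pair(9.0, 5.0)
        cliff = call_cliffs([pair], activities_for(pair))[0]
        (annotated,) = annotate_privileged(
            [cliff], [PrivilegedSubstructure("methyl", "[CH3]")]
        )
        # naphthalene core has no methyl; pattern lives in the substituents only
        assert "ps" not in annotated.categories

    def test_annotation_is_monotone_in_the_library(self):
        cliff = self._cliff("c1ccc2ncccc2c1")
        with_one = annotate_privileged([cliff], [QUINOLINE])[0]
        with_two = annotate_privileged([cliff], [QUINOLINE, INDOLE])[0]
        assert "ps" in with_one.categories and "ps" in with_two.categories

    def test_largest_matching_pattern_is_reported(self):
        cliff = self._cliff("c1ccc2ncccc2c1")
        pyridine = PrivilegedSubstructure("pyridine", "c1ccncc1")
        (annotated,) = annotate_privileged([cliff], [pyridine, QUINOLINE])
        assert annotated.ps_smarts == QUINOLINE.pattern
        assert set(annotated.ps_matches) == {pyridine.pattern, QUINOLINE.pattern}


class TestExtension:
    def _set_and_cliff(self, extra_members):
        pair = make_pair(9.0, 5.0)  # potent C1 = *C@0, weak C2 = *Cl@4
        cliff = call_cliffs([pair], activities_for(pair))[0]
        members = [pair.a, pair.b] + extra_members
        analog_set = AnalogSet("T1", CORE, 10, tuple(members))
        return cliff, analog_set

    def test_both_repositioned_isomers_give_full_status(self):
        cliff, s = self._set_and_cliff([
            member("C3", "*C", 4, 7.0),   # potent's substituent at weak's site
            member("C4", "*Cl", 0, 6.0),  # weak's substituent at potent's site
        ])
        ext = extend_ds_cliff(cliff, s)
        assert ext.extension_status == "full"
        assert ext.iso_of_potent.compound_id == "C3"
        assert ext.iso_of_weak.compound_id == "C4"

    def test_single_isomer_gives_partial_status(self):
        cliff, s = self._set_and_cliff([member("C3", "*C", 4, 7.0)])
        ext = extend_ds_cliff(cliff, s)
        assert ext.extension_status == "partial"
        assert ext.iso_of_weak is None

    def test_no_isomer_gives_none_status(self):
        cliff, s = self._set_and_cliff([])
        ext = extend_ds_cliff(cliff, s)
        assert ext.extension_status == "none"
        assert ext.iso_of_potent is None and ext.iso_of_weak is None

    def test_cliff_members_cannot_serve_as_their_own_isomers(self):
        # iso cliff: the weak compound already is the repositioned potent one
        pair = make_pair(9.0, 5.0, pair_type="iso")
        cliff = call_cliffs([pair], activities_for(pair))[0]
        s = AnalogSet("T1", CORE, 10, (pair.a, pair.b))
        assert extend_ds_cliff(cliff, s).extension_status == "none"

    def test_extension_slots_refragment_to_the_cliff_core(self, fixture_runner):
        from cliffminer.fragmenter import fragment_compound

        result, _ = fixture_runner(4)
        smiles_of = {a.compound_id: a.canonical_smiles for a in result.activities}
        checked = 0
        for ext in result.cliffs:
            core = ext.cliff.pair.core_smiles
            for slot in (ext.iso_of_potent, ext.iso_of_weak):
                if slot is None:
                    continue
                frags = fragment_compound(smiles_of[slot.compound_id], slot.compound_id)
                assert any(
                    f.core_smiles == core
                    and f.substituent_smiles == slot.substituent_smiles
                    and f.position_class == slot.position_class
                    for f in frags
                )
                checked += 1
        assert checked > 0

    def test_extend_all_uses_each_cliffs_own_set(self):
        cliff, s = self._set_and_cliff([member("C3", "*C", 4, 7.0)])
        (ext,) = extend_all([cliff], [s])
        assert ext.extension_status == "partial"
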