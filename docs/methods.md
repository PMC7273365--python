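# Methods

## Problem and model

`cliffminer` identifies activity cliffs (ACs) among analog pairs that
differ at **two substitution sites** of a shared core, and categorizes
them as dual-site (ds), isomer (iso) and privileged-substructure (PS)
cliffs. The underlying similarity model is substructure-based: two
compounds are analogs when single-cut fragmentation maps both onto the
same hydrogen-capped core, each carrying its substituent at a different
core position (each compound implicitly carries H at the other's site).
The potency criterion is a constant, class-independent threshold of at
least 100-fold, applied to assay-independent equilibrium constants (Ki)
only; ΔpKi ≥ 2 with pKi = −log10 Ki[M]. IC50 values are deliberately
unsupported, since they are not comparable across assays.

## Ingest and standardization

High-confidence filtering keeps measurements with assay relationship
type `D` (direct binding), assay confidence score 9, measurement type
`Ki`, relation `=`, and a configurable organism (default `Homo
sapiens`). Structures are standardized with the RDKit
`MolStandardize` machinery: largest organic fragment, charge
neutralization, canonical SMILES. Stereochemistry present in the input
is preserved through standardization.

The aggregation of replicate measurements is a documented default, not a
constraint inherited from the data model: each Ki is converted to molar
(accepted units: `nM`, `µM`/`uM`, `M`, case-insensitive; anything else
raises a unit error, or is routed to the rejects when the pipeline runs
with `skip_unknown_units`), converted to pKi, and averaged per
(standardized structure, target). Groups whose pKi values span more than
`pki_spread_max` (default 1.0 log unit) are discarded entirely — with a
2-log cliff criterion this guarantees that no reported cliff can be an
artifact of irreproducible measurements. Structures appearing under
several accessions collapse to the lexicographically smallest accession,
so a pair always involves two distinct structures.

## Fragmentation and position classes

Every acyclic single bond between two heavy atoms is cut, one bond at a
time, yielding exactly two fragments (ring bonds and bonds to hydrogen
are never cut). "Acyclic single bond" includes chain–chain bonds: cutting
ethylbenzene at the CH2–CH3 bond is what makes toluene a valid core with
a methyl substituent. A cut qualifies when the larger fragment (core) has
at least `core_ratio` (default 2.0) times the heavy atoms of the smaller
(substituent) and the substituent has at most `max_sub_atoms` (default
13) heavy atoms. The core is re-capped with hydrogen at the cut position
(R → H) and canonicalized; the substituent keeps a dummy-atom attachment
point, so attachment regiochemistry *within* the substituent is part of
its identity.

Attachment positions are compared by **symmetry class**: the canonical
atom-rank equivalence class (RDKit `CanonicalRankAtoms` without tie
breaking) of the capped atom, computed on the re-parsed canonical core so
the label depends only on the core's graph, never on input atom
numbering. This is what makes "different sites" chemically meaningful:
all six benzene positions share one class, so benzene-core analogs can
never form a dual-site pair, while 1- and 2-substituted naphthalenes
differ. Whether the original two-site analyses compared positions by
atom identity or by automorphism class is not documented anywhere we
know of; symmetry classes are our choice, and the reconstruction
property (re-attaching the substituent at a class representative
regenerates the parent) is tested to hold under it.

Stereocenters destroyed by a cut are left unassigned in the fragments;
core matching then operates on canonical strings including any remaining
stereochemistry, which prevents enantiomeric cores from matching
spuriously.

## Analog pairs, deduplication, cliff calling

Analog sets group decompositions by (target, core); sets with fewer than
two compounds are dropped. Within a set, all unordered pairs with
distinct compounds, distinct position classes and substituent size
difference ≤ `max_size_diff` (default 8 heavy atoms) qualify; the pair is
`iso` when the attachment-labeled substituent strings are equal and `ds`
otherwise. A compound pair may qualify through several alternative cores
(e.g. both a naphthalene and a methylnaphthalene decomposition); it is
counted **once** per target, represented by the largest shared core
(ties: lexicographically smallest SMILES) and classified by that core's
decomposition, with all supporting (core, type) combinations retained as
evidence. Without this rule, cliff counts would be inflated by multiple
decompositions of the same two molecules.

Cliff calling keeps pairs with ΔpKi ≥ log10(`min_fold`) − 1e−9; the
epsilon makes the "at least 100-fold" boundary robustly inclusive under
floating-point pKi arithmetic. Every cliff carries the `ds` category;
`iso` is added for isomer pairs (iso-ACs are a special case of ds-ACs,
so reported counts decompose additively as iso + non-iso-ds).

## Privileged substructures

PS patterns are inputs (one SMARTS per line, named, deduplicated,
validated at load). Matching for the `ps` category runs by default
against the **shared capped core**, which guarantees the substructure is
present in both cliff compounds; `either`/`both` whole-molecule scopes
are available as configuration because the alternative reading ("the AC
contains a PS" evaluated on the full molecules) is equally defensible.
When several patterns match, all are recorded and the largest by heavy
atoms is reported. `screen_frequency` implements the library-curation
step — keeping patterns found in ≥ `min_count` (default 100) unique
standardized structures — as a separate operation (`ps-screen`); the
pipeline itself does not re-screen, because frequency screens are
defined against a full compound database, not against the slice being
analyzed. The packaged starter library is a synthetic stand-in of
common privileged cores, intended to be replaced by a curated set.

## Extension of ds cliffs

For each cliff, the analog set is searched for the two repositioned
isomers: core + potent compound's substituent at the weak compound's
position class, and vice versa. Isomer candidates must be distinct
compounds from both cliff members (for iso-ACs the repositioned isomer
of one member *is* the other member, so iso-ACs extend to `none`).
Status is `full` (both found), `partial` (one) or `none`. Each found
isomer carries its own pKi, so the four-compound structure supports
position-contribution analysis downstream.

## Synthetic fixtures and what they show

The generator emulates the data regime the search assumes: analog series
on two-ring scaffolds (naphthalene and quinoline by default — one
privileged core, one not) with small substituents (1–3 heavy atoms)
placed at two topologically distinct positions, one measurement per
compound and target, all rows passing the high-confidence filters. The
potency model is a per-series baseline (default pKi 6.5 ± 0.3) plus
uniform noise (default amplitude 0.4, required < 0.5) and a planted
offset (default 3.0, required ≥ 2.0) for randomly chosen potent
compounds; with the defaults, every potent/weak pair across positions is
a cliff with margin and no unplanted pair comes near the threshold. The
defaults (2 targets, 3 substituents per position, 1 potent compound per
series, one shared substituent across positions so isomer pairs exist)
are fixed study conditions, not tuning knobs.

Ground truth is computed by an independent brute-force enumerator over
the generation metadata — all compound pairs, direct rule checks on
position, substituent identity, size difference and the actually
assigned pKi values — never by the pipeline under test. Template
positions are verified distinct by a probe-molecule identity check
(equivalent positions would make the two mono-substituted probes the
same molecule), and single-substituent compounds on mutually
non-derivable scaffolds guarantee that the only core two series members
share is the bare scaffold, so the combinatorial truth is exact.

What passing fixture tests does **not** show: behaviour on ChEMBL-scale
chemical space (multiply substituted molecules, overlapping analog
series, replicate and conflicting measurements, exotic salts), pattern
libraries beyond the starter set, or stereochemistry-rich series. The
corruption modes (wrong relation, low confidence, foreign units, salt
forms) cover the ingest failure paths but not structurally pathological
inputs. Full-scale behaviour is exercised only via
`scripts/reproduce_chembl.py` on user-supplied exports, whose counts are
reported, not asserted.

## Numerical and degenerate-input choices

* Cliff threshold: ΔpKi ≥ 2 − 1e−9 (inclusive boundary, float-safe).
* pKi is exact arithmetic on −log10; no rounding until serialization
  (tables print two decimals; stage dumps carry six to keep staged and
  end-to-end runs byte-identical).
* Empty input tables produce empty outputs and exit 0; a zero-byte file
  is treated as an empty table.
* Equal-size fragments can never satisfy the 2:1 core rule, so a cut
  always has a unique core.
* Output tables are sorted by (target, compound pair) with sequential
  cliff identifiers, making repeated runs byte-identical.
* Problem sizes in the test suite and acceptance script — ~24-compound
  fixtures across 20 seeds, 200 random molecules (≤ 20 heavy atoms) for
  the fragmentation oracle — are chosen as the smallest sets that
  exercise every rule and both category overlaps.

## Known limitations

* Single-cut decomposition only; pairs differing at more than two sites,
  single-site (classic MMP) cliffs, and cliffs against confirmed-inactive
  analogs are out of scope.
* Chirality cliffs are excluded by design: iso-ACs are confined to
  constitutional isomers.
* The aggregation policy (mean pKi, 1-log spread cut) and the PS match
  scope are defensible defaults exposed as configuration, not uniquely
  determined by the problem statement.
* The starter PS library is illustrative; frequency screening against a
  large compound collection is required to reproduce a curated set.
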