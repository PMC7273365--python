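# cliffminer

Unified mining of **dual-site**, **isomer** and **privileged-substructure
activity cliffs** from flat compound-activity tables.

An *activity cliff* (AC) is a pair of structurally analogous compounds
active against the same target whose potencies differ by a large margin —
here at least 100-fold, i.e. ΔpKi ≥ 2 with pKi = −log10 Ki [M]. Such pairs
pinpoint the small chemical changes that dominate structure–activity
relationships, which makes systematically cataloguing them valuable to
medicinal chemists. Classic matched-molecular-pair cliffs differ at a
*single* substitution site; `cliffminer` searches instead for analog pairs
differing at **two** sites of a shared core and sorts the resulting cliffs
into three overlapping categories:

* **ds-AC** (dual-site): different substituents at different core positions;
* **iso-AC** (isomer): the *same* substituent at two different core
  positions — the compounds are constitutional isomers, and every iso-AC
  is by definition also a ds-AC;
* **PS-AC**: a cliff whose shared core contains a *privileged
  substructure*, a recurrent core with family-directed binding behaviour
  (indole, quinoline, biphenyl, …), supplied as a SMARTS pattern library.

The search pipeline is:

1. **Ingest** — read a TSV/CSV activity table (ChEMBL export headers by
   default, remappable), keep only high-confidence measurements (direct
   binding assays, relationship type `D`, confidence score 9, exact `=`
   Ki values, human targets), standardize structures (salt stripping,
   neutralization, canonical SMILES) and aggregate replicate Ki values to
   one mean pKi per compound and target (discarding compounds whose
   replicates span more than 1 log unit).
2. **Fragment** — cut every acyclic single bond between heavy atoms,
   one cut at a time, producing an H-capped core and a substituent. A cut
   qualifies when the core carries ≥ 2× the substituent's heavy atoms and
   the substituent has ≤ 13 heavy atoms. Attachment positions are
   identified by graph-symmetry classes of the capped core.
3. **Pair** — group compounds by (target, core) into analog sets and
   enumerate all pairs whose substituents sit at *different* symmetry
   classes with a size difference ≤ 8 heavy atoms; deduplicate so each
   compound pair counts once per target.
4. **Call cliffs** — keep pairs with ΔpKi ≥ 2 (inclusive), assign
   categories, and annotate privileged substructures on the shared core.
5. **Extend** — for each ds-AC, search its analog set for the two
   repositioned isomers (the potent compound's substituent at the weak
   compound's site and vice versa), yielding a four-compound data
   structure (`full`/`partial`/`none`) that resolves position-specific
   contributions to cliff formation.

## Worked example

The package ships a synthetic-fixture generator that builds small analog
series with planted cliffs, so the whole pipeline can be exercised (and
its output checked against known ground truth) without any download:

```bash
cliffminer simulate --seed 1 --out-dir demo        # writes activities.tsv + truth_pairs.tsv
cliffminer run --activities demo/activities.tsv --out-dir demo/out
```

The run prints, among others:

```
n_compounds=22
n_targets=2
n_aps=36
n_acs=12
n_iso_acs=3
n_noniso_ds_acs=9
n_ps_acs=6
n_ext_full=2
n_ext_partial=6
n_ext_none=4
```

meaning: the 22 fixture compounds on 2 targets form 36 qualifying
two-site analog pairs, of which 12 are activity cliffs; 3 of those are
isomer cliffs and 9 are non-isomer dual-site cliffs (3 + 9 = 12, since
iso-ACs are a subset of ds-ACs); 6 cliffs sit on a quinoline core and are
therefore PS-ACs under the starter pattern library; 2 cliffs could be
fully extended with both repositioned isomers, 6 with one, 4 with none.
The per-cliff table `demo/out/cliffs.tsv` lists, for every cliff, its
categories, both compounds' identifiers/SMILES/pKi values, ΔpKi, the
shared core decomposition, the matched privileged substructure and the
extension isomers:

```
ac_id     target_id  categories  cpd1_id   cpd1_smiles      cpd1_pki  cpd2_id   cpd2_smiles        cpd2_pki  delta_pki  core_smiles
AC000001  T-01       ds          CPD-0005  Cc1ccc2ccccc2c1  9.97      CPD-0001  CCCc1cccc2ccccc12  6.63      3.34       c1ccc2ccccc2c1
```

Each stage is also available as its own subcommand (`filter`,
`fragment`, `pairs`, `cliffs`, `extend`, `ps-screen`) reading and writing
TSV dumps, so intermediates can be inspected and re-run independently.
For real data, point `cliffminer run` at your own activity export (see
`scripts/reproduce_chembl.py` for a full-scale ChEMBL-export run) and
supply a curated pattern library with `--ps-library`; the packaged
starter library is a stand-in.

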