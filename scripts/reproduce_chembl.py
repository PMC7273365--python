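#!/usr/bin/env python
"""Run the full cliff search on a local ChEMBL activity export.

The desk-scale tests in this repository run on synthetic fixtures; this
script is the path to a full-scale reproduction against real data. It
expects a flat activity export (TSV/CSV with the standard ChEMBL headers,
see ``cliffminer.data_ingest.DEFAULT_COLUMNS``) that you have downloaded
yourself — no network access is attempted — plus a privileged-substructure
pattern file, and reports the resulting counts without asserting them::

    python scripts/reproduce_chembl.py --activities chembl_ki_export.tsv \
        --ps-library my_patterns.tsv --out-dir results/chembl

Exact agreement with published full-scale counts depends on unstated
standardization details of the source pipeline and on the pattern set
used; the summary is printed for comparison, not checked.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from cliffminer import pipeline as pl
from cliffminer.ps_library import starter_library_path


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--activities", type=Path, required=True)
    parser.add_argument("--ps-library", type=Path, default=None)
    parser.add_argument("--out-dir", type=Path, default=Path("results/chembl"))
    args = parser.parse_args()

    args.out_dir.mkdir(parents=True, exist_ok=True)
    config = pl.RunConfig(
        activities_path=args.activities,
        ps_library_path=args.ps_library or starter_library_path(),
        out_dir=args.out_dir,
    )
    result = pl.run_pipeline(config, verbose=True)
    pl.write_cliff_table(result.cliffs, result.activities, args.out_dir / "cliffs.tsv")
    pl.write_summary(result.summary, args.out_dir / "summary.txt")
    pl.write_rejects(result.rejects, args.out_dir / "rejects.tsv")
    for key, value in result.summary.items():
        print(f"{key}={value}")


if __name__ == "__main__":
    main()
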