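"""Privileged-substructure libraries and frequency screening.

Privileged substructures (PSs) are recurrent core structures with a
tendency of preferential binding to particular target families. They are
inputs here, not discovered: a library file lists one pattern per line
(``NAME<TAB>SMARTS``, ``#`` comments), and :func:`screen_frequency`
retains the patterns found in a minimum number of unique standardized
structures (default 100) of the working compound set.

The packaged starter library (``data/ps_starter_library.tsv``) is a
synthetic stand-in holding common privileged cores from the medicinal
chemistry literature (indole, quinoline, biphenyl, benzimidazole, ...);
replace it with your own curated pattern set for production analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

from .data_ingest import CompoundActivity
from .errors import ConfigurationError


@dataclass(frozen=True)
class PrivilegedSubstructure:
    name: str
    pattern: str
    n_compounds: int = 0


@lru_cache(maxsize=4096)
def compile_pattern(pattern: str) -> Chem.Mol:
    """Compile a SMARTS (or SMILES) pattern into a substructure query."""
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise ConfigurationError(f"invalid substructure pattern: {pattern!r}")
    return query


def pattern_heavy_atoms(pattern: str) -> int:
    return sum(1 for a in compile_pattern(pattern).GetAtoms() if a.GetAtomicNum() != 1)


def starter_library_path() -> Path:
    """Path of the packaged stand-in PS library."""
    return Path(str(resources.files("cliffminer") / "data" / "ps_starter_library.tsv"))


def load_ps_definitions(path: str | Path) -> list[PrivilegedSubstructure]:
    """Load and validate a pattern file; duplicate patterns collapse to one.

    Invalid patterns raise :class:`ConfigurationError` naming the line.
    """
    entries: list[PrivilegedSubstructure] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, pattern = line.rpartition("\t")
            pattern = pattern.strip()
            name = name.strip() or f"PS{lineno}"
            try:
                query = compile_pattern(pattern)
            except ConfigurationError:
                raise ConfigurationError(
                    f"invalid pattern at line {lineno} of {Path(path).name}: {pattern!r}"
                ) from None
            canonical = Chem.MolToSmarts(query)
            if canonical in seen:
                continue
            seen.add(canonical)
            entries.append(PrivilegedSubstructure(name=name, pattern=pattern))
    return entries


def screen_frequency(
    ps_list: Sequence[PrivilegedSubstructure],
    compounds: Iterable[CompoundActivity],
    min_count: int = 100,
) -> list[PrivilegedSubstructure]:
    """Keep patterns contained in at least ``min_count`` unique structures.

    Uniqueness is by standardized structure, not compound identifier, so a
    structure listed under several accessions counts once.
    """
    unique_structures = sorted({c.canonical_smiles for c in compounds})
    mols = [Chem.MolFromSmiles(s) for s in unique_structures]
    kept = []
    for ps in ps_list:
        query = compile_pattern(ps.pattern)
        n = sum(1 for m in mols if m is not None and m.HasSubstructMatch(query))
        if n >= min_count:
            kept.append(replace(ps, n_compounds=n))
    return kept
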