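"""Shingle frequency tables: build, persist, query.

The table maps each shingle string to the number of *molecules* in a
reference corpus that contain it at least once (presence counts, not
total occurrences: each molecule's shingle set is deduplicated before
counting).  Shingles seen in fewer than ``min_count`` molecules are
dropped — rare substructures carry no statistical signal and bloat the
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

from .shingles import (
    CANONICALIZATION_TAG,
    MoleculeRecord,
    ParseError,
    Standardizer,
    parse_molecule,
    shingle_texts,
)

log = logging.getLogger(__name__)

_META_FIELDS = (
    "corpus_name",
    "n_molecules",
    "n_parse_failures",
    "min_count",
    "min_radius",
    "max_radius",
    "canonicalization_tag",
)
_INT_META = {"n_molecules", "n_parse_failures", "min_count", "min_radius", "max_radius"}


class TableFormatError(ValueError):
    """A table file is malformed or its metadata is missing/invalid."""


@dataclass
class ShingleFrequencyTable:
    """Mapping shingle text -> molecule presence count, with provenance."""

    entries: dict[str, int] = field(default_factory=dict)
    corpus_name: str = ""
    n_molecules: int = 0
    n_parse_failures: int = 0
    min_count: int = 100
    min_radius: int = 1
    max_radius: int = 3
    canonicalization_tag: str = CANONICALIZATION_TAG

    def lookup(self, shingle_text: str) -> Optional[int]:
        """Stored count for a shingle, or ``None`` if absent (never 0)."""
        return self.entries.get(shingle_text)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShingleFrequencyTable):
            return NotImplemented
        return self.entries == other.entries and self.meta == other.meta

    @property
    def meta(self) -> dict:
        return {k: getattr(self, k) for k in _META_FIELDS}


def build_reference(
    corpus: Iterable[Union[MoleculeRecord, str]],
    min_count: int = 100,
    min_radius: int = 1,
    max_radius: int = 3,
    corpus_name: str = "",
    dedupe: bool = False,
    standardizer: Optional[Standardizer] = None,
) -> ShingleFrequencyTable:
    """Tabulate shingle frequencies over a reference corpus.

    Each molecule increments a shingle's count at most once; entries with
    final count < ``min_count`` are dropped.  Items may be records or raw
    SMILES strings; unparseable strings are skipped and counted in
    ``n_parse_failures``.  With ``dedupe``, exact structural duplicates
    (identical canonical SMILES) contribute only once.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    n_mols = 0
    n_failures = 0
    seen: set[str] = set()
    for item in corpus:
        if isinstance(item, str):
            try:
                record = parse_molecule(item, standardizer=standardizer)
            except ParseError as err:
                n_failures += 1
                log.warning("skipping unparseable corpus record: %s", err)
                continue
        else:
            record = item
        if dedupe:
            from rdkit import Chem

            key = Chem.MolToSmiles(record.mol)
            if key in seen:
                continue
            seen.add(key)
        n_mols += 1
        for text in shingle_texts(record, min_radius, max_radius):
            counts[text] = counts.get(text, 0) + 1
    if n_mols == 0 and n_failures > 0:
        log.warning("all %d corpus records failed to parse; table is empty", n_failures)
    return ShingleFrequencyTable(
        entries={s: c for s, c in counts.items() if c >= min_count},
        corpus_name=corpus_name,
        n_molecules=n_mols,
        n_parse_failures=n_failures,
        min_count=min_count,
        min_radius=min_radius,
        max_radius=max_radius,
    )


def save_table(table: ShingleFrequencyTable, path: Union[str, TextIO]) -> None:
    """Write a table as UTF-8 TSV: '#key<TAB>value' metadata header lines
    in fixed order, then one 'shingle<TAB>count' line per entry in
    lexicographic key order (byte-stable round trip)."""
    if isinstance(path, str):
        with open(path, "w", encoding="utf-8") as fh:
            save_table(table, fh)
        return
    for key in _META_FIELDS:
        path.write(f"#{key}\t{getattr(table, key)}\n")
    for shingle in sorted(table.entries):
        path.write(f"{shingle}\t{table.entries[shingle]}\n")


def load_table(path: Union[str, TextIO]) -> ShingleFrequencyTable:
    """Read a table written by :func:`save_table`.

    Raises :class:`TableFormatError` on missing metadata, malformed
    lines, or counts below the declared cutoff.
    """
    if isinstance(path, str):
        with open(path, encoding="utf-8") as fh:
            return load_table(fh)
    meta: dict[str, object] = {}
    entries: dict[str, int] = {}
    for lineno, raw in enumerate(path, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            key, sep, value = line[1:].partition("\t")
            if not sep or key not in _META_FIELDS:
                raise TableFormatError(f"line {lineno}: unrecognized header {line!r}")
            meta[key] = int(value) if key in _INT_META else value
            continue
        shingle, sep, count = line.partition("\t")
        if not sep or not shingle:
            raise TableFormatError(f"line {lineno}: expected 'shingle<TAB>count'")
        try:
            entries[shingle] = int(count)
        except ValueError:
            raise TableFormatError(f"line {lineno}: bad count {count!r}") from None
    missing = [k for k in _META_FIELDS if k not in meta]
    if missing:
        raise TableFormatError(f"missing metadata header(s): {', '.join('#' + m for m in missing)}")
    table = ShingleFrequencyTable(entries=entries, **meta)  # type: ignore[arg-type]
    bad = [s for s, c in entries.items() if c < table.min_count]
    if bad:
        raise TableFormatError(f"{len(bad)} entries below declared min_count={table.min_count}")
    return table
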