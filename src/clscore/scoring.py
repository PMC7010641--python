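"""CLscore: mean log10 reference frequency over a molecule's shingles.

For a molecule with N unique shingles of which m are present in the
reference table with frequencies f_S,

    CLscore = ( sum over matched shingles of log10 f_S ) / N

Unmatched shingles contribute zero to the numerator but still count in
the denominator, so the score rewards molecules built entirely from
substructures common in the reference corpus.  With presence counts
f_S >= 1 the score is always >= 0, and it is bounded above by
log10(corpus size).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .shingles import MoleculeRecord, ParseError
from .table import ShingleFrequencyTable
from .shingles import shingle_texts

log = logging.getLogger(__name__)


class TagMismatchError(RuntimeError):
    """Molecule and table were canonicalized under different conventions."""


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-molecule scoring detail."""

    n_shingles: int  #: N — unique shingles in the molecule
    n_matched: int  #: m — shingles found in the reference table
    log_sum: float  #: sum of log10(f_S) over matched shingles
    clscore: float


@dataclass
class StreamCounters:
    """Summary counters accumulated by :func:`score_stream`."""

    scored: int = 0
    passed: int = 0
    parse_failures: int = 0


def score_molecule(mol: MoleculeRecord, table: ShingleFrequencyTable) -> ScoreBreakdown:
    """Score one parsed molecule against a reference table.

    Refuses to score when the molecule was canonicalized under a
    different convention than the table (the shingle strings would not be
    comparable).  Zero-shingle molecules (single heavy atom) score 0.
    """
    if mol.canonicalization_tag != table.canonicalization_tag:
        raise TagMismatchError(
            f"molecule tag {mol.canonicalization_tag!r} != table tag "
            f"{table.canonicalization_tag!r}"
        )
    texts = shingle_texts(mol, table.min_radius, table.max_radius)
    n = len(texts)
    if n == 0:
        log.debug("molecule %s has no shingles; score 0 by definition", mol.id)
        return ScoreBreakdown(n_shingles=0, n_matched=0, log_sum=0.0, clscore=0.0)
    log_sum = 0.0
    matched = 0
    for text in texts:
        count = table.lookup(text)
        if count is not None:
            matched += 1
            log_sum += math.log10(count)
    return ScoreBreakdown(
        n_shingles=n, n_matched=matched, log_sum=log_sum, clscore=log_sum / n
    )


def score_stream(
    records: Iterable[MoleculeRecord],
    table: ShingleFrequencyTable,
    cutoff: Optional[float] = None,
    counters: Optional[StreamCounters] = None,
) -> Iterator[tuple[MoleculeRecord, ScoreBreakdown]]:
    """Score a record stream, optionally filtering to clscore >= cutoff.

    Order-preserving.  Pass a :class:`StreamCounters` to collect summary
    counts (scored / passed / parse failures); parse failures can only
    arise when the input iterable raises :class:`ParseError` lazily.
    """
    if cutoff is not None and cutoff < 0:
        raise ValueError("cutoff must be >= 0 (scores are non-negative)")
    if counters is None:
        counters = StreamCounters()
    iterator = iter(records)
    while True:
        try:
            record = next(iterator)
        except StopIteration:
            return
        except ParseError:
            counters.parse_failures += 1
            continue
        breakdown = score_molecule(record, table)
        counters.scored += 1
        if cutoff is None or breakdown.clscore >= cutoff:
            counters.passed += 1
            yield record, breakdown
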