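"""End-to-end pipeline: build reference -> score/filter -> bin -> sample.

Mirrors the generation of a likeness-filtered, evenly sampled subset of
a large SMILES collection: a frequency table is built from a reference
corpus, queries are scored and filtered at a cutoff, survivors are
binned by property triplet, and a fixed-size subset is drawn evenly
across bins.  Every artifact is written as plain text next to a JSON
run manifest; partially written files keep a ``.partial`` suffix until
their stage completes.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .fixtures import (
    DEFAULT_SCAFFOLDS,
    CorpusSpec,
    QuerySpec,
    generate_query_set,
    generate_reference_corpus,
    iter_records,
)
from .sampler import allocate_uniform, census_stream, compute_triplet, draw_sample
from .scoring import StreamCounters, score_stream
from .table import build_reference, save_table
from .shingles import parse_molecule


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run."""

    outdir: str
    min_count: int = 100
    cutoff: Optional[float] = 3.3
    cutoff_percentile: Optional[float] = None  # overrides cutoff when set
    target: int = 500
    seed: int = 0
    reference_multiplicity: int = 120
    n_queries: int = 5000
    reference_scaffolds: Sequence[str] = field(default_factory=lambda: DEFAULT_SCAFFOLDS)

    @property
    def n_reference(self) -> int:
        return len(self.reference_scaffolds) * self.reference_multiplicity


@dataclass
class PipelineResult:
    table_entries: int
    n_scored: int
    n_passed: int
    cutoff_used: float
    retention: float  #: fraction of scoreable queries at or above the cutoff
    n_sampled: int
    manifest_path: str


def _write_lines(path: str, lines) -> None:
    partial = path + ".partial"
    with open(partial, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
    os.replace(partial, path)


def run_end_to_end(config: PipelineConfig) -> PipelineResult:
    """Execute build-ref -> score/filter -> bin -> sample, writing artifacts."""
    t0 = time.time()
    os.makedirs(config.outdir, exist_ok=True)
    path = lambda name: os.path.join(config.outdir, name)

    corpus_spec = CorpusSpec(
        scaffolds=[(s, config.reference_multiplicity) for s in config.reference_scaffolds],
        shuffle_seed=config.seed,
    )
    ref_lines = generate_reference_corpus(corpus_spec)
    _write_lines(path("reference.smi"), ref_lines)

    table = build_reference(
        iter_records(ref_lines), min_count=config.min_count, corpus_name="synthetic-fixture"
    )
    partial = path("table.tsv.partial")
    save_table(table, partial)
    os.replace(partial, path("table.tsv"))

    query_spec = QuerySpec(n_molecules=config.n_queries, seed=config.seed + 1)
    query_lines = generate_query_set(query_spec)
    _write_lines(path("queries.smi"), query_lines)

    counters = StreamCounters()
    scored = list(score_stream(iter_records(query_lines), table, counters=counters))
    scores = np.array([b.clscore for _, b in scored])
    if config.cutoff_percentile is not None:
        cutoff = float(np.percentile(scores, config.cutoff_percentile)) if len(scores) else 0.0
    else:
        cutoff = float(config.cutoff if config.cutoff is not None else 0.0)
    survivors = [(r, b) for r, b in scored if b.clscore >= cutoff]
    _write_lines(
        path("scored.tsv"),
        (
            f"{r.smiles}\t{r.id}\t{b.clscore:.6f}\t{b.n_shingles}\t{b.n_matched}"
            for r, b in survivors
        ),
    )
    retention = len(survivors) / len(scored) if scored else 0.0

    survivor_records = [r for r, _ in survivors]
    census = census_stream(iter(survivor_records))
    _write_lines(
        path("census.tsv"),
        (
            f"{k.hac}\t{k.stereo_class}\t{k.hetero_class}\t{census.counts[k]}"
            for k in sorted(census.counts)
        ),
    )
    allocation = allocate_uniform(census, config.target)
    keyed = ((compute_triplet(r), f"{r.smiles}\t{r.id}") for r in survivor_records)
    sample = list(draw_sample(keyed, allocation, config.seed))
    _write_lines(path("sample.smi"), sample)

    manifest = {
        "tool_version": __version__,
        "seed": config.seed,
        "min_count": config.min_count,
        "cutoff_used": cutoff,
        "cutoff_percentile": config.cutoff_percentile,
        "target": config.target,
        "n_reference": len(ref_lines),
        "table_entries": len(table),
        "n_queries": len(query_lines),
        "n_scored": counters.scored,
        "n_parse_failures": counters.parse_failures,
        "n_passed": len(survivors),
        "retention": retention,
        "n_bins": len(census.counts),
        "n_sampled": len(sample),
        "runtime_s": round(time.time() - t0, 3),
    }
    manifest_path = path("manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(
        table_entries=len(table),
        n_scored=counters.scored,
        n_passed=len(survivors),
        cutoff_used=cutoff,
        retention=retention,
        n_sampled=len(sample),
        manifest_path=manifest_path,
    )
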