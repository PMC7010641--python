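# Methods

## Shingles

A molecular *shingle* of radius `r` rooted at atom `a` is the connected
fragment induced by every bond within `r` breadth-first steps of `a`
(a bond's depth is one plus the topological distance of its nearer
endpoint from the root), serialized as a canonical SMILES string whose
writing starts at `a`. Radii 1–3 are enumerated, i.e. circular
substructures up to a diameter of six bonds — the environments
underlying ECFP4-class fingerprints. Radius 0 (bare atoms) is excluded.
An environment that does not extend to the full requested radius is not
emitted: its fragment is already produced at its true radius rooted at
the same atom, so the unique set is unchanged (the test suite checks
this "truncation neutrality" directly). Note the bond-depth convention
matters in small rings: in cyclopropane every atom is within distance 1
of every other, yet the ring-closing bond lies at depth 2, so the
whole ring appears as a radius-2 shingle.

Parsing conventions, all recorded in a *canonicalization tag* carried by
both tables and parsed molecules (scoring refuses to mix tags):

* aromaticity is perceived under RDKit's default model and written in
  lowercase aromatic form;
* all stereochemistry is removed before extraction, so shingle strings
  never contain `@`, `/` or `\`, and stereoisomers share one shingle
  set;
* implicit hydrogens are not written; formal charges and isotopes are
  rendered as parsed (no protonation normalization is performed — a
  user-pluggable `standardizer` hook can transform SMILES before
  parsing for corpora that need it);
* every molecule is round-tripped through its canonical stereo-free
  SMILES before extraction. This pins a deterministic atom order:
  rooted canonical SMILES of *fragments* (which may contain aromatic
  atoms outside a complete ring and cannot be sanitized standalone) is
  otherwise sensitive to the parent's atom numbering, and canonical-rank
  renumbering still leaks input order through tie-breaking. With the
  round-trip, the shingle set is invariant to how the input SMILES was
  written, which the suite verifies over seeded random renderings.

Multi-fragment (dot-separated) input is handled per component and the
shingles pooled uniquely.

## Frequency table

`f_S` is the number of reference molecules whose shingle set contains
`S` — presence counting, not occurrence counting: a molecule with two
symmetric copies of an environment contributes 1. Entries with final
count below `min_count` (default 100) are dropped; the cutoff lives in
the table, never re-applied at scoring time. Exact duplicate structures
in the corpus are counted separately by default (the table mirrors raw
corpus statistics); `dedupe` collapses them first. The on-disk format is
deterministic UTF-8 TSV — fixed-order `#key<TAB>value` metadata headers,
then entries in lexicographic key order — so save/load round trips are
byte-stable and table files diff cleanly.

## Score

For a query with `N` unique shingles, `m` of them in the table with
frequencies `f_S`:

```
CLscore = ( Σ_{i=1..m} log10 f_Si ) / N
```

`N` counts *unique* shingles (the same fragment string found at several
roots counts once), matching the unique counting used to build the
table. Logarithms are base 10; no alternative base is offered. A
molecule with no shingles (single heavy atom) scores 0 by definition
rather than raising a division error. Since `1 ≤ f_S ≤ n_molecules`,
scores satisfy `0 ≤ CLscore ≤ log10(n_molecules)`. Stream filtering at
a cutoff keeps records with `clscore ≥ cutoff`, inclusive.

## Triplet bins and even sampling

Each molecule maps to `(HAC, min(stereo, 5), min(hetero, 8))`:

* `HAC` — heavy (non-hydrogen) atom count, not range-capped; the module
  is generic over molecule size.
* `stereo` — potential tetrahedral stereocenters (assigned plus
  unassigned, symmetry-aware perception), because enumerated collections
  carry mostly unassigned centers; a flag restricts to assigned-only,
  which re-reads the original input rendering since the engine strips
  stereo at parse time. Counts ≥ 5 merge into class 5.
* `hetero` — heavy atoms that are not carbon; counts ≥ 8 merge into
  class 8.

Both merge thresholds are configurable.

The allocator sorts bins by ascending size and iterates: the remaining
target divided by the number of remaining bins gives the current quota;
every bin no larger than the quota is taken whole and subtracted from
the target; when the smallest remaining bin exceeds the quota, all
remaining bins receive `floor(quota)` and the shortfall is distributed
+1 per bin in ascending-size order (ties by lexicographic key) until the
allocation sums to exactly `min(target, total)`. Taking bins at
size = quota whole versus leaving them to the constant-quota step
provably yields the same allocation, and the `floor` + top-up rule can
never oversample a bin (any remaining bin has size strictly above the
fractional quota, hence at least `floor(quota) + 1`). Consequences
verified as invariants: conservation, no oversampling, all non-exhausted
bins within ±1 of each other, and exhaustion ordering (a bin taken whole
during iteration is never larger than any open bin's quota; a bin filled
exactly by the +1 top-up may exceed it by that one record — with sizes
{1, 1} and target 1 no conserving allocation can do better).

Per-bin draws use reservoir sampling (Algorithm R), uniform without
replacement, with the bin's RNG seeded by `crc32(seed | bin key)` —
stable across runs, platforms and input arrival order of other bins.
Output lists bins in lexicographic key order, records in draw order;
repeat runs with one seed are byte-identical, and spill-file and
streaming draws agree exactly. For streams too large for memory the
census phase can spill each bin's records to its own file, making the
census → allocate → draw phases restartable from disk.

## Synthetic fixtures

The reference-corpus generator replicates scaffold SMILES at chosen
multiplicities and shuffles with a seed, so every table count is known
in advance: a shingle unique to scaffold `s` gets exactly
`multiplicity(s)`, shared shingles the sum over sharing scaffolds. The
default scaffold set spans homologous series (alkanes, alcohols/ethers,
amines, methylated benzenes and small heteroaromatics) so overlap with
query molecules is controllable by construction.

The query generator draws from four weighted families — random acyclic
alkane skeletons (attachment trees respecting valence), the same
skeletons with O or N substitutions (alcohols/ethers, amines), and small
aromatic cores with random substituents — over a configurable heavy-atom
range (default 3–17). All randomness flows from explicit seeds; repeat
runs are byte-identical. These fixtures emulate the *statistical shape*
the pipeline needs (controlled shingle multiplicities, a broad spread of
scores, ≥ 10 occupied triplet bins per 100 molecules) but not real
chemistry: no rings beyond the fixed aromatic cores, no charges,
isotopes or exotic valences, and a substructure vocabulary far smaller
than a real bioactivity corpus. Passing tests therefore demonstrate
correctness of the machinery, not performance of the score on real
libraries.

## Problem sizes and defaults

The end-to-end configuration used by the acceptance script runs a
reference corpus of 500 molecules (25 scaffolds × multiplicity 20),
5,000 queries, the score cutoff placed at the queries' empirical
60th-percentile (so retention is 40% by construction, up to ties at the
boundary), and a sampling target of 500; it completes in well under a
minute on one CPU. The `min_count` default of 100 and the score-cutoff
default of 3.3 are the field's reference operating points for this
score; both are plain parameters. Percentile cutoffs use linear
interpolation (`numpy.percentile`), and retention is reported over
scoreable (parseable) queries.

## Known limitations

* Shingle strings are tied to the toolkit's aromaticity model and
  canonical writer; tables are not portable across RDKit versions with
  changed canonicalization (the tag check turns silent drift into a
  hard error).
* Fragment SMILES are not guaranteed to re-parse as standalone
  molecules (aromatic atoms outside complete rings); they are verbatim
  dictionary keys, not chemistry objects.
* Presence counting saturates: a corpus dominated by one scaffold family
  yields a small table and coarse score resolution.
* The in-memory census assumes the number of *bins* is small (it is by
  construction: merged classes bound it), but streaming draws hold one
  reservoir per bin — quota × bins lines — in memory.
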