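# clscore

Substructure-frequency likeness scoring and stratified uniform sampling
for large SMILES collections.

## The problem

Exhaustively enumerated chemical databases contain orders of magnitude
more molecules than have ever been made, and most of them are far too
complex to be realistic synthesis targets. A practical way to carve a
tractable, synthetically plausible subset out of such a collection is to
ask, for every candidate molecule, *how much of it is built from
substructures that occur frequently in known bioactive compounds* — and
then to sample the survivors evenly across molecular size and
complexity instead of inheriting the enumeration's exponential skew
toward the largest, most complex structures.

This package implements that workflow for any user-supplied reference
corpus:

1. **Shingle extraction** — every circular substructure (*molecular
   shingle*) of bond radii 1–3 around every atom, serialized as a
   canonical aromatic SMILES string rooted at the central atom, with all
   stereochemistry discarded. These are the atom environments that
   underlie ECFP-style fingerprints, kept as verbatim strings rather
   than hashed.
2. **Reference table** — shingle → frequency over a reference corpus,
   where the frequency `f_S` of shingle `S` is the number of corpus
   molecules containing it at least once; shingles seen in fewer than
   `min_count` molecules (default 100) are dropped.
3. **Scoring** — the likeness score of a query molecule with `N` unique
   shingles, `m` of which match the table:

   ```
   CLscore = ( Σ_{i=1..m} log10 f_Si ) / N
   ```

   Unmatched shingles contribute nothing to the numerator but still
   count in `N`, so the score is the mean log-frequency of the
   molecule's substructure vocabulary in the reference corpus.
   Streams can be filtered at a cutoff (`clscore >= c`, inclusive).
4. **Binning and even sampling** — survivors are stratified by the
   triplet (heavy atom count, stereocenter class, heteroatom class),
   with stereocenter counts ≥ 5 and heteroatom counts ≥ 8 each merged
   into a single class. An iterative allocator then draws a fixed total
   evenly across bins: bins smaller than the running per-bin quota are
   taken whole and the quota is recomputed over the remaining bins;
   draws within a bin use seeded reservoir sampling, so repeat runs are
   byte-identical.

A synthetic fixture generator (replicated scaffolds with chosen
multiplicities for the reference; random molecules from homologous
families for queries) makes the entire pipeline testable offline with
exactly known shingle statistics.

## Worked example

```python
from clscore import CLScorer, UniformBinSampler

# reference corpus: 150 copies of ethanol
scorer = CLScorer(min_count=100).fit(["CCO"] * 150)
print(len(scorer.table_))              # 5   (ethanol's 5 unique shingles)
print(scorer.table_.lookup("CC"))      # 150

print(scorer.score_samples(["CCO", "CCC", "c1ccccc1"]))
# [2.17609126 0.72536375 0.        ]
```

Ethanol itself matches all 5 of its shingles, each with frequency 150,
so its score is `5·log10(150)/5 = 2.176`. Propane shares only the
two-carbon shingle `CC` (one match out of three unique shingles:
`log10(150)/3 = 0.725`), and benzene shares nothing, scoring 0.

Even sampling, on a population skewed 50/30/5 across three bins:

```python
population = ["CCO"] * 50 + ["CCC"] * 30 + ["c1ccccc1"] * 5
sampler = UniformBinSampler(target=20, seed=3).fit(population)
print(sampler.allocation_.quotas)
# {PropertyTriplet(hac=3, stereo_class=0, hetero_class=1): 7,
#  PropertyTriplet(hac=3, stereo_class=0, hetero_class=0): 8,
#  PropertyTriplet(hac=6, stereo_class=0, hetero_class=0): 5}
```

The 5-molecule benzene bin is exhausted; the remaining 15 draws split
evenly (7/8) across the two larger bins, the +1 going to the smaller of
the two.

The same functionality is exposed as a command-line tool:

```
clscore fixture ref --multiplicity 120 --out ref.smi
clscore fixture query --n 5000 --seed 7 --out q.smi
clscore build-ref --in ref.smi --out table.tsv --min-count 100
clscore score --in q.smi --table table.tsv --out scored.tsv --cutoff 3.3
clscore bin --in scored.tsv --spill-dir bins/ --census census.tsv
clscore sample --spill-dir bins/ --census census.tsv --target 10000 --seed 42 --out sample.smi
```

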