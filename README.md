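# pgsrank

Trait-specific variant and gene rank databases built from PGS Catalog
scoring files by Dowdall reciprocal-rank aggregation.

## The problem

A polygenic score (PGS) assigns each trait-associated variant a signed
per-allele effect weight; the PGS Catalog distributes hundreds of such
scoring files per disease, each nominating a different (partially
overlapping) set of variants with weights on incomparable scales.  Which
variants matter most for a trait *across* its published scores?  Weights
cannot be averaged directly — they come from different models, cohorts and
units — but each score's internal *ordering* of variants is meaningful.

`pgsrank` treats each scoring file as a ballot ranking its variants by
absolute effect weight |w| and aggregates the ballots with the **Dowdall
method**, a Borda-family positional voting rule: the variant at rank *i* in
a file receives a reciprocal rank RR = 1/*i* (1, 1/2, 1/3, …).  A variant's
trait-level score is its **mean reciprocal rank**

```
MRR(v) = (1/N) Σ_{k=1..N} RR_k(v)
```

over the trait's N scoring files, with RR = 0 in files where the variant
is absent or its weight is missing ("NA"); a variant with no usable weight
anywhere has MRR = 0, and MRR = 1 is attained only by the unique
top-weighted variant of every file.  Tied |w| blocks share the mean of
their positions' reciprocals, which preserves the per-file conservation
law Σ RR = H(n), the n-th harmonic number.  Variant MRRs roll up to genes
via a precomputed variant→gene annotation table (ANNOVAR-multianno-style
text): a gene scores the maximum MRR of its annotated variants.  Traits,
scores, variant ranks, gene ranks and per-trait weight summaries are
materialized into a single queryable SQLite file.

Intended users: statistical geneticists and tool builders who want a
reproducible, offline-queryable prioritization of trait variants from
public PGS data.

## Worked example

Generate a small synthetic trait corpus (4 scoring files, 50 variants
each, partially overlapping, 5% missing weights), build a database, and
query it:

```sh
pgsrank gen-fixtures --out corpus --seed 11 --n-files 4 --n-variants 50
pgsrank build-db --scores corpus --out ranks.db
pgsrank top --db ranks.db --trait synthetic -n 5
```

prints

```
trait            variant_key   mrr                  n_present  n_pgs
synthetic trait  rs99454015    0.39038825757575757  4          4
synthetic trait  rs36899312    0.3474206349206349   4          4
synthetic trait  rs78803959    0.31417624521072796  4          4
synthetic trait  1:100373139   0.28238578309735807  4          4
synthetic trait  10:214376158  0.17410714285714285  4          4
```

`rs99454015` is present with a usable weight in all 4 files (`n_present`)
and its reciprocal ranks average to 0.390 over the 4 ballots — e.g. a
variant ranked 2nd, 3rd, 3rd and 2nd would score
(1/2 + 1/3 + 1/3 + 1/2)/4 ≈ 0.417.  Variants are keyed by harmonized rsID
when available, otherwise by GRCh38 `chr:pos`.  `pgsrank summarize --db
ranks.db` prints the per-trait weight range, mean, median and sample
standard deviation over all merged non-missing weights:

```
trait            n_files  w_min    w_max   mean     median     sd      n_rows
synthetic trait  4        -0.6194  0.9245  -0.0080  -9.46e-05  0.1938  189
```

The same workflow runs against real data: `pgsrank fetch --trait
"Alzheimer disease" --cutoff 2023-08-04 --out scores/` discovers the
trait's score accessions through the PGS Catalog REST API (filtered to a
pinned release date), downloads their GRCh38-harmonized scoring files, and
`build-db` proceeds as above.  Fetching needs network access and the
pinning is best-effort (the API serves current state), so catalog-derived
statistics are reported, not asserted.

From Python:

```python
from pgsrank import build_trait_database
db = build_trait_database({"Alzheimer's disease": paths}, "ranks.db")
db.query_top_variants("Alzheimer", 10)   # substring trait match
db.query_top_genes("Alzheimer", 10)      # each gene listed once
```

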