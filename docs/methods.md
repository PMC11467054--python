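# Methods

## Rank aggregation model

Each trait is associated with N scoring files (polygenic scores).  A
scoring file is treated as a ballot over its variants, ordered by the
absolute value of the per-allele effect weight |w|; signs are ignored
because a strongly protective allele is as informative as a strongly
risk-increasing one, and weights across files are on incomparable scales,
so only within-file order is used.  The Dowdall positional rule assigns
position *i* the reciprocal rank RR = 1/*i*.  The trait-level statistic is
the mean reciprocal rank

MRR(v) = (Σ_k RR_k(v)) / N,

where the sum runs over **all** N files and RR_k(v) = 0 when v is absent
from file k or its weight there is missing.  This all-files denominator is
a deliberate choice: it rewards variants that rank highly *consistently*
across scores (the Borda-family convention of summing over all ballots),
rather than variants that appear once with a high rank.  The alternative —
averaging only over files where the variant has a usable weight — is
implemented as `aggregate_mrr_present_only` for comparison; it scores
sporadic variants higher and is not used by the database build.

Ranking is computed per file, never on the pooled row set: pooling would
compare weights across scores, which the model refuses to do.

### Ties and missing weights

Weights originate as decimal text, so tie detection uses exact equality of
the parsed floats (no epsilon): equal text implies equal floats, and an
epsilon would make ranks depend on unrelated rows.  A block of t variants
tied over positions p..p+t−1 shares the mean of 1/p..1/(p+t−1).  This is
deterministic, order-free, and preserves the per-file conservation law
Σ RR = H(n) exactly (up to float addition error, bounded well below 1e−12
at realistic n), which in turn is used as a test invariant.

Cells "NA" are missing weights.  A variant row with missing weight is kept
in the merged dataset — it witnesses the variant's membership in that
score — but is excluded from the file's ranking.  A variant whose weight
is missing in every file still emits a record with MRR 0 rather than being
dropped, so queries can distinguish "known but unweighted" from "unknown".

### Aggregation order

Reciprocal ranks are accumulated over files in sorted accession order, so
the computed MRR is bitwise identical no matter the order in which files
are supplied, not merely equal to ~1 ulp.

## Variant keys and merging

Records are keyed by, in precedence order: harmonized rsID, submitted
rsID, harmonized GRCh38 chr:pos, submitted chr:pos.  rsIDs are
lower-cased with the `rs` prefix enforced; chromosome labels lose any
`chr` prefix and X/Y/MT are upper-cased.  Keys of different forms are
taken at face value: unifying an rsID-keyed row with a coordinate-keyed
row for the same locus would require an external rsID↔position map, which
this package deliberately does not ship — a documented limitation, since a
variant labelled inconsistently across files splits its MRR mass between
two keys.

Merging concatenates all files' rows (no cross-file deduplication — two
files scoring the same variant are two ballots).  Within one file a
duplicate key would let one candidate occupy two ballot positions, so
duplicates are collapsed to the occurrence with the largest |w| (a
non-missing weight always beats a missing one; equal |w| keeps the
earliest row), with a logged warning.

No liftover, strand flipping, or effect-allele reconciliation is
performed; files are expected to be GRCh38-harmonized already.

## Gene rollup

The variant→gene map is consumed as a precomputed ANNOVAR-multianno-style
table; a variant may map to several genes and contributes to all of them.
A gene's score is the **maximum** MRR among its annotated variants, with
the attaining variant recorded as provenance.  Max (rather than sum or
mean) was chosen because a gene is prioritized by its best variant and the
score stays in [0, 1] and independent of gene length; this rollup rule is
this package's own design decision and users comparing against other
gene-ranking schemes should note it.  Genes are unique in every query
result by construction.

## Summary statistics

Per-trait weight summaries (min, max, mean, median, sample sd with the
n−1 denominator) are computed over all merged occurrence rows with a
non-missing weight — a variant present in k files contributes k weights —
matching a bind-rows-then-summarize workflow.  A single observation
reports sd 0 with a `single_observation` flag rather than NA, keeping the
database schema numeric.

## Database

A single SQLite file with five tables (traits, scores, variant_ranks,
gene_ranks, summary), primary-key uniqueness on (trait, variant_key) and
(trait, gene), foreign keys to `traits`, and `PRAGMA user_version` as the
schema version.  Builds are atomic (temp file + rename), so a constraint
violation leaves no partial database.  Query ordering is always score
descending with a lexicographic tie-break, making "top N" reproducible.
Trait lookup is case-insensitive with a substring fallback ("Alzheimer"
matches "Alzheimer's disease"); ambiguity is an error, not a guess.

## Synthetic corpora

The fixture generator emulates the structural features of a trait's real
input: several scoring files with partially overlapping variant sets
(`overlap` = fraction of each file drawn from a shared pool, default 0.5),
signed normal weights (default sd 0.04, the order of magnitude seen in
real disease scores) multiplied by a per-file scale factor drawn
log-uniformly over 10^−2..10^1 so that magnitudes span orders of magnitude
and exercise scientific-notation parsing, missing weights at rate 0.05,
and a mix of rsID- and coordinate-keyed variants (default 30%
coordinates).  Defaults of 5 files × 100 variants reflect a modest trait;
the acceptance script's three-trait build uses 23/5/5 files at 500
variants per file to exercise a larger, asymmetric build in seconds.  An
optional `planted_top` variant is injected into every file with |w|
strictly above the file's maximum, guaranteeing MRR 1 as an end-to-end
ground truth.

The generator does **not** simulate linkage disequilibrium, allele
frequencies, genotypes, or correlated weights between files; passing tests
demonstrate the correctness of parsing, merging, ranking and querying, not
biological validity of any particular ranking.

Determinism: each file derives from its own seeded child stream
(`[seed, file_index]`), so the same seed gives byte-identical corpora
(gzip members are written with mtime 0 and no stored filename) and
extending a corpus with more files never perturbs the earlier ones.

`oracle_mrr` is an independent brute-force reference: per-file ranks are
obtained by pairwise counting (rank = 1 + #strictly-larger |w|), not by
sorting, and share no code with the pipeline.  The acceptance suite checks
pipeline/oracle agreement within 1e−12 over 200 random corpus
specifications.

## Catalog client

The REST client lists score accessions for a trait term and filters them
by release date (default cutoff 2023-08-04) before downloading the
GRCh38-harmonized scoring files.  The API serves current state, so
date-filtering is a best-effort pin: statistics computed from fetched data
are reported, never asserted, and the published per-trait figures can be
approached but not guaranteed (they also depend on whether summaries were
taken over occurrence rows or unique variants, which is ambiguous —
this package uses occurrence rows).  All transport goes through an
injectable callable; the test suite uses mocked transports exclusively and
performs no network access.  Only GRCh38 harmonized files are supported;
GRCh37 and ontology-tree traversal are out of scope.

## Numerical and degenerate-input choices

- Weight text accepts scientific notation; non-finite or non-decimal
  weight text rejects the whole file with the offending row index.
- Missing tokens accepted on input: "NA", "", "."; only "NA" is written.
- Rows with no usable identifier (no rsID, no complete chr:pos) are
  rejected at parse with a reported count; a file with zero usable rows is
  an error.
- An all-missing file contributes an empty ranking (with a warning) and
  still counts in the MRR denominator — it is a cast ballot that ranked
  nobody.
- Floats are serialized with `repr`, the shortest round-tripping form, so
  write→parse is an exact identity on weights.

## Known limitations

- Cross-form key unification (rsID vs coordinates) is not attempted.
- The gene rollup rule (max) and the all-files MRR denominator are design
  choices where published practice is ambiguous; both alternatives are
  either implemented (`aggregate_mrr_present_only`) or documented.
- Catalog reproduction depends on remote state and network access.
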