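# Methods

## Model of the harmonization problem

A biallelic SNP is fully determined by its genomic site (chromosome,
1-based position) and an unordered allele pair drawn from {A, C, G, T}.
What differs between datasets is the *orientation*: which allele is labeled
REF (other allele) and which ALT (effect allele). The package's unit of
truth is the canonical index `CHR:POS:REF:ALT`; two datasets describe the
same variant in the same orientation iff their canonical indices are equal,
and in opposite orientation iff one equals the other's reverse (REF and ALT
swapped). Orientation is a labeling convention, not a biological property,
so any consistent convention is acceptable — the package adopts the first
dataset's convention per site and propagates it.

Preconditions inherited from the problem setting, not checked by the code:
all inputs share one reference assembly and one strand orientation.
Consequently A/T and C/G (palindromic) pairs need no special treatment here;
they are only counted and surfaced in the run summary, because under a
strand *in*consistency they would be silently unfixable.

## The registry

The registry is keyed by genomic position alone. A site admits exactly one
registered allele pair; a dataset later presenting a different pair at a
registered site is classified `ALLELE_MISMATCH`, written to a report and
excluded from realigned output — it is never registered and never
silently kept, since keeping conflicting pairs is precisely the artifact the
pipeline exists to remove. Entries are immutable and the entry set grows
monotonically across runs, which yields two load-bearing properties:

- *orientation stability*: a record classified `FORWARD` stays `FORWARD`
  under any number of subsequent registrations;
- *order sensitivity with convergent outcome*: swapping which dataset runs
  first changes which records are counted as reassigned, but all realigned
  outputs still agree with each other site by site.

Storage is one parquet file per chromosome with columns
(pos, ref, alt, first_seen_dataset, first_seen_id), sorted by position,
plus an append-only JSON manifest recording the creation time and the
ordered list of realign runs. Partitions are loaded lazily and
independently, so chromosome-restricted runs touch one file; a single
writer per registry is assumed, with parallelism available across
chromosomes (`--chrom`) or across distinct registries.

## clean

Bucket precedence, applied in order; the four buckets exactly partition the
input rows:

1. **non_biallelic** — either allele fails to normalize to a single base in
   {A, C, G, T}, or the two are equal. Indel codes (`I`/`D`/`-`/`*`/`.`)
   and multi-base alleles fail here.
2. **invalid_multi_indexed** — the graph rule: one node per distinct
   (chrom, pos); each dataset ID seen at ≥ 2 distinct positions contributes
   edges joining them; all rows at any position incident to an edge are
   invalid. Incidence alone disqualifies, so connected components never
   need to be materialized: a position multimap suffices. clean is run on
   the whole dataset at once so IDs spanning chromosomes are caught.
3. **duplicates** — exact identity on (chrom, pos, a1, a2); the first
   occurrence in file order survives (deterministic, streaming-friendly).
4. **invalid_multi_indexed** (again) — positions still carrying more than
   one distinct allele pair after deduplication are multiallelic *by rows*;
   keeping one row would be an arbitrary orientation choice, so all are
   routed to the invalid report.

A row with an unrecognizable chromosome label raises at the reader
boundary rather than entering a bucket: the buckets classify rows by
allele/ID rules, and an unparseable chromosome means the file needs user
attention, not silent filtering.

## Flipping and statistic correction

Swapping which allele is called "effect" forces the statistic transforms:
beta → −beta, odds ratio → 1/OR, effect-allele frequency → 1 − f. P-values
are invariant (two-sided tests do not depend on allele labeling) and are
never altered. The flip is an involution; round-tripping is exact for the
allele swap and conserves `f + f' = 1` and `β + β' = 0` to 1e-12. Non-finite
effect sizes or frequencies, and an odds ratio of exactly 0, raise rather
than propagate. Genotype-metadata inputs (`.pvar`/`.bim`) carry no
statistics, so flipping only swaps REF/ALT and contributes a row to the
PLINK2 reassignment list. Missing optional statistic columns are simply
left untouched — the flip operates on whatever roles the dataset spec maps.

## merge and intersect

merge requires per-chromosome reports of a single dataset (mixed labels and
repeated chromosomes are errors) and preserves per-chromosome counts so that
composite totals are checkable by additivity. intersect requires composites
from one registry (verified via provenance headers the report files carry)
and is a plain string intersection of canonical-index sets — by the time
intersect runs, orientation is already unified, so finding an index and its
reverse anywhere in the union indicates a realignment defect and aborts
loudly instead of degrading to fuzzy matching. Output is a sorted index
list plus one extract list per dataset keyed by that dataset's original
variant IDs, so genotype files can be subset directly.

## The synthetic cohort generator

The generator emulates the discordance the pipeline targets and nothing
else:

- each cohort indexes the same underlying variants under a different
  dialect (tab-separated sumstats with rsIDs and bare chromosome labels;
  `.pvar` with `chr`-prefixed chromosomes and `CHR_POS_REF_ALT` IDs;
  comma-separated sumstats with `Chr`-prefixed labels);
- a planted fraction of the shared variants (default `flip_rate = 0.434`,
  the discordance scale observed between real prostate-cancer cohorts) is
  written in inverted orientation *self-consistently* — alleles swapped,
  beta negated, frequency complemented — so each file is internally valid
  and only cross-dataset comparison reveals the inversion;
- data-quality corruptions (IDs planted at two positions; exact duplicate
  rows) are planted disjointly from one another, in the first cohort;
- genotype dosages are two independent Bernoulli draws per sample at the
  variant's effect-allele frequency (Hardy–Weinberg), stored in true
  orientation and keyed by canonical index; the file-orientation view
  (`recorded_dosages`) complements the flipped columns;
- a liability phenotype is the genetic score over shared variants plus
  Gaussian noise scaled to a heritability knob (default 0.5).

What the generator does *not* emulate — linkage disequilibrium, imputation
error, strand flips, assembly mismatches, indels — bounds what passing
tests show: they certify bookkeeping-exact harmonization of
strand-consistent biallelic SNPs, not robustness to upstream QC failures.
LD in particular is omitted deliberately: harmonization operates row-wise,
so correlation between variants cannot change any count the pipeline
reports, and its absence keeps the oracle checks exact.

Default problem sizes (12,000 variants, 10,000 shared, 1,000 samples in the
acceptance script; a few hundred to a few thousand in tests and examples)
are chosen so every check runs in seconds while keeping counts large enough
that bookkeeping errors cannot hide in rounding; all generation is
deterministic given the seed, to the byte.

## Numerical and formatting choices

- Realigned summary statistics preserve the input's column layout; only
  flipped values are rewritten, formatted at `%.10g`. A `CANONICAL_ID`
  column is appended (also to `.pvar` outputs, which tolerate extra
  columns; `.bim` keeps its rigid six columns and relies on the identified
  report for the ID mapping).
- All outputs are sorted by (chromosome in natural order 1..22, X, Y, MT;
  then position), and no data file embeds a timestamp, so identical inputs
  produce identical outputs.
- Chromosome aliases are resolved by a fixed table (`chr`/`Chr`/`CHR`
  prefixes stripped; `M` → `MT`; PLINK numeric codes 23/24/25 → X/Y/MT).
  Non-autosomal codes X/Y/MT are accepted throughout.
- Coordinates are 1-based everywhere (VCF/.pvar/.bim convention), enforced
  at the reader boundary.

## Known limitations

- Only biallelic SNPs are harmonized; indels and multiallelic sites are
  reported for manual follow-up.
- No strand inference: a strand-flipped non-palindromic pair at a
  registered site surfaces as `ALLELE_MISMATCH`, and a strand-flipped
  palindromic pair is undetectable from alleles alone.
- One writer per registry; no registry merging or deletion.
- The `.pgen`/`.bed` binary genotype payloads are never touched — the
  reassignment list delegates the actual allele recoding to PLINK2.
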