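# allelign

Cross-dataset harmonization of biallelic SNP indexing and REF/ALT
(effect/other) allele assignments for GWAS summary statistics and genotype
metadata.

## The problem

Multi-cohort genetic analyses — GWAS meta-analyses, validation studies, and
the development and portability of polygenic risk scores (PRS) — require
that every dataset agree on (a) how a variant is identified and (b) which
allele is labeled REF vs ALT (in summary statistics: other vs effect
allele). In practice datasets index variants however they like (rsIDs,
`CHR_POS_REF_ALT` concatenations, `chr`-prefixed or bare chromosome labels)
and assign REF/ALT arbitrarily. Left uncorrected, swapped allele labels
create illusory allele-frequency divergence between cohorts and silently
corrupt any effect-size-weighted computation: a PRS adds dosage *d* where it
should add *2 − d*.

`allelign` fixes this for biallelic SNPs, the variant class that dominates
genetic studies. It assumes all inputs already share a reference assembly
and strand orientation (it does no liftover and no strand inference);
indels, multiallelic sites and other variant classes are reported, not
harmonized.

## The method

Every variant row is reduced to a canonical index

```
CHR:POS:REF:ALT
```

where the effect allele plays the ALT role. A persistent **registry** —
one parquet partition per chromosome, created empty — records the
authoritative orientation of each site the first time any dataset
contributes it. Each dataset is then passed through **realign**, which runs
three stages:

1. **clean** — identifies valid biallelic SNPs and resolves indexing
   pathologies by a graph formulation: positions are nodes, and any dataset
   ID occurring at ≥ 2 positions connects them with edges; every position
   touched by an edge is invalid. Exact duplicate rows keep their first
   occurrence; positions carrying more than one allele pair are routed to
   the invalid report.
2. **register** — classifies each surviving record against the registry:
   `FORWARD` (consistent), `REVERSE` (alleles swapped relative to the
   registry — marked for realignment), `NOVEL_POSITION` (queued for
   addition), or `ALLELE_MISMATCH` (conflicting allele pair — reported and
   excluded).
3. **align** — flips the REVERSE records. Swapping allele labels must also
   transform the statistics that refer to them: beta → −beta (or odds ratio
   → 1/OR), effect-allele frequency → 1 − f; p-values are untouched. Novel
   records are registered, and realigned outputs plus per-chromosome report
   files (identified / reassigned / duplicates / invalid / mismatched) are
   written. For `.pvar`/`.bim` genotype inputs it also writes a two-column
   allele-reassignment list consumable by PLINK2.

Because the registry grows monotonically and entries are immutable, every
dataset realigned later is consistently oriented with all earlier ones.
**merge** combines a dataset's per-chromosome reports into a composite, and
**intersect** computes the maximal set of canonical indices common to all
composites, with per-dataset extract lists keyed by each dataset's original
IDs.

The package also ships a synthetic-cohort generator
(`allelign.simulate`) that plants known inversions, multi-indexed IDs and
duplicate rows into discordantly-formatted cohort files, with an oracle
truth ledger and Hardy–Weinberg genotype dosages — every pipeline guarantee
is testable against planted truth, no data download required.

## Worked example

```bash
python examples/01_realign_two_cohorts.py
```

```
cohortA: identified=2000 reassigned=0 registered=2000 invalid=10 duplicates=5
cohortB: identified=2000 reassigned=400 registered=400 invalid=0 duplicates=0
planted inversions in cohortB: 400
registry now holds 2400 sites
```

cohortA is realigned first against a fresh registry, so by definition it
reassigns 0 SNPs and registers all 2000; its 5 planted multi-indexed IDs
(2 rows each) and 5 duplicate rows land in the report buckets. cohortB —
same variants, different indexing dialect, 400 planted REF/ALT inversions —
reports exactly 400 reassigned and registers only its 400 cohort-private
variants. `examples/02_merge_and_intersect.py` and
`examples/03_prs_restoration.py` continue the story: the intersection
recovers the planted shared set exactly, and harmonization restores PRS
score vectors to their oracle values (error ~5e-14) while naive scoring is
off by whole dosage units.

The same workflow is available from the shell:

```bash
allelign init --root registries --name study
allelign realign --registry registries/study --input gwas.tsv --format sumstats \
    --label gwas --col-chrom CHR --col-pos BP --col-id SNP --col-ea EA \
    --col-oa OA --col-beta BETA --col-eaf EAF --effect-scale beta --outdir out
allelign realign --registry registries/study --input cohort.pvar --format pvar \
    --label cohort --outdir out
allelign merge --label cohort --reports out/cohort/chr1.identified.tsv ... --out cohort.composite.tsv
allelign intersect --composites gwas.composite.tsv --composites cohort.composite.tsv --out intersection
```

Dataset order matters: the first dataset realigned defines the registry
orientation, so run your anchor dataset (typically the summary statistics
whose effect alleles you want everything aligned to) first.

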