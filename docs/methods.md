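# Methods

## Scope and model

`pathburden` analyses a case/control cohort of called, annotated exome
variants. It deliberately begins *after* alignment, variant calling and
functional annotation: the inputs are a multi-sample VCF (GT/DP per
genotype, QUAL and INFO/MQ per site), an ANNOVAR-multianno-style TSV of
per-variant annotations, a two-column sample→group file, and GMT pathway
definitions. Nothing upstream (read QC, BWA, GATK, VQSR, ANNOVAR) is
re-implemented.

The analysis has three layers:

1. a seven-rule filter cascade selecting rare, deleterious, protein- or
   splice-affecting variants;
2. gene- and pathway-level enrichment of the mutated-gene set via the
   hypergeometric upper tail;
3. carrier-rate summaries (per gene and per pathway, per group) and a
   demographics table.

## Carrier semantics

A sample *carries* a variant iff its genotype is het or hom-alt. Missing
genotypes count as non-carriers for every rate (they remain visible in the
genotype matrix for auditing). Where per-sample DP is available, a carrier
call additionally requires that sample's depth strictly above the depth
cutoff; samples with missing DP fall back to the genotype alone. The
site-level part of the quality rule (MQ, QUAL) gates the whole record,
while the depth part is per-sample: a record with no sample above the depth
cutoff is removed outright (reason `depth`). Multi-allelic sites are split
into one record per ALT allele; a sample's genotype for an allele is the
number of its chromosomes carrying it.

## Filter cascade

All thresholds live in `FilterThresholds` (defaults in parentheses), every
inequality strict unless stated:

| rule | condition to keep | parameters |
|---|---|---|
| quality | depth > 4 in ≥1 sample, MQ > 30, QUAL > 20 | `min_depth_exclusive` (4), `min_mapping_quality_exclusive` (30), `min_site_qual_exclusive` (20) |
| rarity | every *present* panel MAF < 0.01 | `max_maf_exclusive` (0.01) |
| region | exonic / exonic;splicing, or splicing with junction distance ≤ 10 bp | `splice_window_bp` (10) |
| synonymous | not a synonymous SNV, unless dbscSNV flags splice relevance | — |
| repeat indel | not (non-frameshift indel, length < 10 bp, in a repeat) | `repeat_indel_max_len_exclusive` (10) |
| consensus | ≥ 3 of 4 predictors vote harmful | `consensus_votes_required` (3), `cadd_deleterious_cutoff` (20) |
| splice distance | not (splicing, > 2 bp from junction, no predicted splice effect) | `splice_distance_removal_bp` (2) |

Design decisions where the procedure was genuinely open:

- **"More than half of four" = ≥ 3 votes.** Two of four is exactly half,
  not more.
- **Missing predictor calls cast no vote and the 3-vote bar is not
  lowered.** A variant with ≥ 2 predictors missing can therefore never
  pass the consensus — this includes indels, which SIFT/PolyPhen do not
  score. Conservative and reproducible; users who want a different policy
  can lower `consensus_votes_required`.
- **CADD needs a numeric cutoff** to become a categorical vote; the
  package uses phred-scaled 20 (a common working threshold) and exposes it
  in the config rather than hiding it.
- **Missing MAF counts as rare.** Absence from large population panels is
  itself evidence of rarity.
- **The > 2 bp splice rule** is scoped to splicing-region records and uses
  dbscSNV relevance as the "affects alternative splicing" oracle, the only
  splice-effect annotation in the input. The reference point for the
  distance is the annotated distance to the nearest splice junction.
- **Indel length** follows the VCF allele convention,
  `max(len(ref), len(alt)) − 1`.

Every predicate is pure and record-local, so the set of survivors is
invariant under any permutation of stage order and the cascade is
idempotent; only the *attribution* of removals (first failing stage in the
chosen order) depends on the order. The `FilterTrace` satisfies, at every
stage, `in − kept = Σ reason counts`, with `in(first) = |input|` and
`kept(last) = |output|`.

## Enrichment

For a group (cases or controls), a background gene is *mutated* when ≥ 1
group sample carries ≥ 1 surviving variant in it. With `N` background
genes, `n` mutated, `M` in the pathway and `m` mutated in the pathway, the
pathway p-value is `P(X ≥ m)` for `X ~ Hypergeometric(N, M, n)` — the
upper tail of the draw of the mutated genes from the background. `m = 0`
gives exactly 1. The tail is summed in log space (log-gamma terms combined
with `logsumexp`), exact to ~1e−12 against rational-arithmetic evaluation
and stable for backgrounds up to ~1e5 genes.

- **Background universe**: by default the union of all loaded gene sets;
  an explicit background list should be supplied when the pathway-annotated
  universe is larger than the sets under study (it usually is).
- **Mutated genes outside the background do not enter `n`.**
- **Per-group testing**: enrichment is computed separately for cases and
  controls, since the motivating design reports them separately.
- **Boundary rule**: enriched ⇔ p ≤ α, inclusive, with a 1e−9 relative
  tolerance on the comparison so a p mathematically equal to α is not
  pushed to the wrong side by floating-point rounding.
- **Gene-level enrichment flags** (inputs to the pathway positivity rule)
  apply the same tail to a singleton set: for one gene, p = n/N when the
  gene is mutated and 1 otherwise, so a gene is enriched iff it is mutated
  and the mutated fraction n/N ≤ α. In the regime this analysis targets —
  thousands of pathway-annotated background genes of which a few percent
  are mutated post-filter — this reduces to "the gene carries a qualifying
  mutation". A pathway is *positive* iff ≥ 1 of its genes is flagged;
  genes without a flag count as not enriched.
- **No multiple-testing correction is applied to the headline columns**;
  a Benjamini–Hochberg column (`q_case_bh`) is emitted alongside, clearly
  separate, for users screening many pathways.
- The report is sorted by case p-value, ties broken by pathway id, so
  reruns are byte-stable.

Rates: `gene_mutation_rate = carriers(gene, group) / |group|`;
`pathway_carrier_rate = carriers(any pathway gene, group) / |group|`. The
pathway rate always dominates each member gene's rate.

## Demographics

The group-by-sex 2×2 table is tested with the uncorrected Pearson
chi-square (closed form `N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))`, 1 df);
the Yates correction is available but off by default, because only the
uncorrected statistic reproduces the published p of 0.47 on the 75/42 vs
46/32 sex split. Age is continuous, so a chi-square is not applicable as
printed in the motivating study; the table offers Welch's t-test for age
and labels it as this package's method choice. Zero-margin tables (e.g. an
all-male cohort) report the sex p as not applicable rather than erroring
the whole table.

## Synthetic cohorts

The generator emulates exactly the statistical structure the analysis
consumes:

- **Carrier model**: per gene and group, each sample is a carrier with a
  configured probability; each carrier receives `1 + Poisson(λ)` planted
  qualifying variants (λ = `extra_variants_mean`, default 0.6, so a carrier
  typically has 1–2 qualifying sites). Sites are shared between carriers
  of the same gene with probability `site_sharing_prob` (0.3), giving a mix
  of recurrent and private sites.
- **Qualifying variants pass all seven predicates by construction**: MAFs
  drawn from a Beta(0.5, 400) truncated below 0.01 with cross-panel
  correlation (a shared base value jittered per panel, ~30% of panel
  entries missing), exonic nonsynonymous/stopgain consequence, ≥ 3 harmful
  predictor votes (each predictor votes harmful with probability 0.95 for
  a planted deleterious variant; draws below 3 votes are topped up, since
  the variant is deleterious by construction), depths 10–250 for carriers,
  MQ 40–70, QUAL 50–1500.
- **Contaminants** fail exactly one designated rule and pass all others,
  one reason code per rule (`depth`, `mapping_quality`, `site_qual`, `maf`,
  `region`, `synonymous`, `repeat_indel`, `consensus`, `splice_distance`),
  so the cascade's removals can be checked record-for-record against the
  emitted `TruthManifest`.
- **Coordinates** live on a toy contig: gene *i* owns positions
  `[i·100000+1, i·100000+50000]`. No reference genome is involved.
- **Demographics** come from configurable normals (ages), exponential
  (illness duration), normal (HAMD), and either Bernoulli sex draws or
  exact per-group female counts.
- All randomness flows from one `numpy.random.Generator` seeded by the
  config; emitted files are byte-identical across reruns.

What the generator does *not* emulate — and therefore what passing tests
do not show about real data: linkage disequilibrium, realistic site
frequency spectra, correlated annotation errors, batch effects between
groups, relatedness, population stratification, or calling/genotyping
error processes. Tests against it certify the *pipeline*, not any
biological claim.

### Canned scenarios

- `studylike_scenario()` — a **shape-alike** of the motivating study, not
  a regeneration of its data: 117 cases vs 78 controls; the six-gene
  carbohydrate pathway embedded with case carrier probabilities 0.76 /
  0.77 / 0.82 for the amylases and 1.0 for SI/MGAM/LCT, zero in controls;
  994 background genes mutated at equal rates in both groups, with the
  per-sample rate (2.6e−4) chosen so ~3% of background genes are mutated
  per group — the small-n/N regime of a pathway-annotated exome cohort;
  sex counts fixed at 75/42 and 46/32; five contaminants per filter rule.
- `null_config()` / `null_cohort()` — identical carrier probabilities in
  both groups and pathways that are arbitrary gene blocks, for type-I
  error work.

### Type-I-error calibration

`null_enrichment_positive_rate()` measures the achieved level of the
enrichment call on no-structure cohorts. Frozen study conditions
(`NULL_CALIBRATION`): 60 samples per group, 400 genes, pathways of
30/40/60/80 genes, per-sample carrier probability `1 − 0.6^(1/60)` so each
gene is mutated in ≥ 1 group sample with probability 0.4. Under gene
exchangeability, `m | n` is exactly hypergeometric, so the p-value is
exact but discrete; mixing over the binomial `n` across replicates
smooths the discreteness. An exact (non-Monte-Carlo) evaluation of these
conditions puts the achieved level at 0.034–0.040 — below the nominal
0.05, as expected for a discrete test, and inside the [0.03, 0.07] band
the calibration test asserts over 2000 Monte-Carlo replicates. The
replicates use a sample-level fast path (`null_mutated_gene_replicates`)
that draws the carrier matrix and feeds the resulting mutated-gene sets to
the same enrichment routine the full pipeline calls.

## Numerical and degenerate-input choices

- Hypergeometric input invariants (`0 ≤ m ≤ min(n, M)`, `M, n ≤ N`) are
  enforced at construction; violations are domain errors, not clamped.
- Empty filter input yields an empty output and a zero-count trace.
- Rates over an empty group are domain errors (no silent NaN).
- `describe_group` uses the n−1 sample SD and flags it unavailable for a
  single observation.
- Sorting keys (report by (p, pathway_id), variants by (pos, alt)) are
  total, so all emitted artifacts are deterministic.

## Problem sizes

The shipped scenarios are sized for a laptop: the study-shaped cohort is
195 samples × ~1000 variants (a full simulate→filter→enrich run takes
~1 s), the calibration experiment 2000 replicates of a 120-sample,
400-gene null cohort (~3 s), and the exhaustive hypergeometric oracle
check covers every parameter combination up to N = 25. These sizes are the
package's own choice of test scale; every routine also handles
exome-scale inputs (the tail is validated to N = 1e5).

## Known limitations

- The consensus rule effectively excludes indels unless MutationTaster and
  CADD plus a third vote are present; see above.
- The splice rules depend entirely on the annotation table's
  `splice_distance_bp` and dbscSNV columns; no transcript model is
  consulted.
- Gene-level enrichment flags are a degenerate (M = 1) use of the pathway
  statistic; in small backgrounds where the mutated fraction exceeds α no
  gene can be flagged, and positivity then reflects that regime honestly
  rather than being forced.
- The multi-allelic split keeps per-ALT records independent; a sample het
  for two different ALTs counts as a carrier of each.
- No relatedness, ancestry or covariate adjustment: the enrichment test
  assumes exchangeable genes and independent samples.
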