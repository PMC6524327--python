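# Methods

## Model

The package scores the integrity of gene *g* in individual *h* as

S_gh = − Σ_i D_i · log10(f_i1 · f_i2),

summing over the variants the individual carries in the gene. The model is
deliberately mixed: multiplicative across the two alleles of one diploid
locus (the frequencies of both observed alleles multiply inside the log,
so a homozygote scores exactly twice a rare heterozygote in the rare-allele
limit) and additive across loci within a gene, reflecting the cumulative,
non-Mendelian action of many small effects in complex disease. The log link
upweights rarity; deleteriousness D enters linearly.

Assumptions worth stating explicitly:

* **No phase, no interaction.** Contributions add regardless of whether two
  heterozygous variants sit in cis or trans; compound heterozygosity and
  dominance beyond the frequency product are not modelled.
* **Frequencies are population priors**, not cohort estimates. The score
  uses annotated reference-database frequencies; the reference allele gets
  1 − Σ(alt) so multi-allelic sites are exact.
* **One deleteriousness metric at a time.** The matrix is computed per
  metric; metrics are not combined.

## Parameters

| parameter | default | units | why |
| --- | --- | --- | --- |
| frequency floor | 1e-5 | allele fraction | the rarest frequency resolvable in large exome repositories; also bounds a single-variant contribution at 10 (homozygous) / ~5 (heterozygous) |
| median targeted length | 1461 | bp | a typical cohort-median targeted gene length; keeps corrected scores on a familiar scale. Recomputable from the supplied regions (`--recompute-median`) since it is cohort-specific by construction |
| metric bounds | see `geneburden/data/metrics.yaml` | raw-score units | bounded metrics use their native (0, 1); the five unbounded metrics use the extreme values observed across dbNSFP v3.3a; PROVEAN uses its documented −14..14 range |
| histogram bin width | 0.01 | score | fine enough to isolate the single-variant spikes at 0.602 and 5.0 |
| tail fraction q | user-set | fraction | matched to the expected carrier fraction of the gene under test (e.g. 0.03 for a gene causal in ~3% of patients) |

## Numerical and edge-case choices

* **Clamping, not rejection.** Raw metric values outside the configured
  bounds (possible with newer annotation databases) are clamped before
  rescaling, keeping D in [0, 1].
* **Missing is missing.** A variant without a metric annotation contributes
  nothing to that metric's score (different metrics annotate different gene
  sets); no imputation. MutationTaster without its prediction class is
  treated as missing because its direction rule cannot be evaluated.
  Missing genotypes (`./.`) contribute nothing — unobserved is not
  homozygous-reference evidence, but it scores the same (zero).
* **PROVEAN** is rescaled from (−14, 14) to [0, 1] and *then* complemented,
  so raw −14 (most deleterious) maps to D = 1, consistent with every other
  metric's directionality.
* **Heterozygous-alt genotypes** (e.g. 1/2 at a multi-allelic site) take
  the maximum D over the observed, scoreable alt alleles — a conservative
  single-D summary of a genuinely two-allele genotype; frequencies still
  use both observed alleles.
* **Multi-gene annotations** (`GENE1;GENE2`) contribute to each listed
  gene independently.
* **Hemizygosity** (male X, and by extension Y and mitochondrial
  single-allele calls) squares the single observed allele's frequency,
  i.e. is treated as homozygous.
* **Zero-variance genes** in Z-profiling return Z = 0 with a warning; an
  all-zero matrix reports its coefficient of variation as missing.
* Scores accumulate in double precision; matrices are written with six
  significant digits, enough for the 0.60206 anchor to survive a
  round-trip.

## Statistics

Group comparisons use the Mann-Whitney U test with midranks and the
tie-corrected normal approximation — gene-score vectors are heavily
zero-inflated, so tie handling is the operative detail. For tie-free groups
of ≤ 8 the exact null distribution is used instead. The extreme-tail test
selects the top ceil(q·n) scores *within each group independently*
(values tied with the cut are all kept, avoiding an arbitrary drop rule),
then applies the one-tailed test. With q = 1 it reduces exactly to the
one-tailed full test. No multiple-testing correction is applied by default;
a Bonferroni column over the genes tested is emitted alongside.

Calibration under a zero-inflated null and power under a minority-carrier
alternative are exercised in the test suite (2000 simulated null genes at
n = 100 per group; 200 replicates of a 170 vs 170 cohort where 30% of cases
and 5% of controls carry a rare D = 0.9 heterozygote). These sizes were
chosen as the smallest at which the binomial Monte-Carlo bands are tight
enough to be informative.

## What the synthetic generator does and does not emulate

`simulate_cohort` emits a complete, self-consistent input bundle: VCF with
per-sample genotypes drawn at Hardy-Weinberg proportions (allele picks per
chromosome, one pick for males at X-linked genes), ANNOVAR-style sidecar
annotations whose raw metric values are generated by *inverting* each
metric's transform so the normalisation layer is genuinely exercised, two
deliberately offset capture-kit BEDs whose intersection equals the gene
spans, a gene model, phenotype and sex tables, and a ground-truth score
matrix computed by a direct, independent implementation of the equation.
Output is a pure function of the configuration; reruns are byte-identical.

Defaults describe a modest case/control exome study: 170 cases and 170
controls, ~50 genes with targeted lengths log-normally spread around the
1461 bp median, 8 variants per gene with log-uniform MAFs between 1e-4 and
0.5, uniform deleteriousness, 5% truncating / 10% synonymous / 5% splicing
classes, 10% multi-allelic sites. A causal stanza plants one rare damaging
variant with different carrier fractions in cases and controls — the
known-positive-gene design used to validate the score.

Deliberately **not** emulated: linkage disequilibrium, a realistic site
frequency spectrum, ascertainment noise between sampling and annotated
frequencies (a knob exists but defaults to zero), annotation errors,
batch/capture-kit depth artefacts, and population structure. Passing
end-to-end tests therefore demonstrates correctness of the scoring
arithmetic and plumbing, not robustness to the quality-control hazards of
real cohorts — contamination checks, relatedness pruning, depth
harmonisation and ethnicity matching remain upstream responsibilities.

The archetype cohort is a separate, degenerate design — every gene carries
exactly one variant of one of the two canonical types (common homozygous
D = 1, MAF 0.5; rare heterozygous D = 1, MAF 1e-5), every sample a carrier —
used to reproduce the two-spike structure of uncorrected score histograms
and its dispersal under length correction.

## Open design points, as resolved here

* Per-gene (not per-transcript) scoring, keyed on gene symbol, matching
  gene-level annotation practice.
* Frequencies come from a single configured population column; switching
  populations is a configuration choice, not ingest logic.
* "Targeted length" counts all targeted bp overlapping the supplied gene
  model, UTR probes included if the model includes them.
* Rank-score variants of metric columns (e.g. fathmm-MKL rank scores) are
  not accepted interchangeably with raw scores; bounds are per-column and
  user-overridable instead.
* A minimum-depth mask is supported as just another BED in the
  intersection list; depth computation from alignments is out of scope.

## Limitations

Scores are only comparable across samples processed with the same capture
regions, annotation database versions, and metric configuration. The
truncating override treats all protein-truncating variants as equally and
maximally damaging. Synonymous and splicing variation is excluded even
where metrics could score it. The score is descriptive, not a calibrated
probability of pathogenicity.
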