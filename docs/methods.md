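# Methods

This note records the statistical model behind `icibench`, the
conventions the implementation fixes where the field admits variants,
and what the synthetic cohort does and does not emulate.

## Stratification and TMB

A sample is **mutant** for the query gene iff it carries at least one
*nonsynonymous* somatic variant: one of
`Missense_Mutation, Nonsense_Mutation, Nonstop_Mutation, Frame_Shift_Del,
Frame_Shift_Ins, Splice_Site, Translation_Start_Site`. In-frame indels
and all non-coding classes are excluded from both the mutation call and
TMB; unknown `Variant_Classification` tokens are rejected rather than
dropped, and samples present in the mutation file but absent from the
sequencing manifest abort the run (an unsequenced patient must never be
silently read as wildtype). Gene symbols are compared case-insensitively
after upper-casing; no alias resolution is attempted. Gene-*set* status
(e.g. the NOTCH family `NOTCH1–4`, the homologous-repair set
`ATR, ATM, BRCA1, BRCA2, MUTYH`) uses the union rule: altered iff any
member gene qualifies.

**TMB** = nonsynonymous count / exonic footprint, in mutations/Mb. The
footprint is per-assay: WES 38 Mb; the 468/410/341-gene targeted panels
1.22/1.06/0.98 Mb. The same six-class filter is used for the mutation
call and for TMB — whether in-frame indels belong in a TMB numerator is
genuinely ambiguous in practice, and using one filter keeps the two
quantities consistent. Samples without assay metadata default to WES
with a logged warning.

## Clinical endpoints

ORR counts RECIST best response CR or PR. DCB is CR/PR **or SD lasting
strictly more than 6 months**; SD of exactly 6.0 months is NDB (the
definition is "lasted > 6 months", taken literally). SD records must
carry a duration; other responses must not. PFS/OS times are consumed
as already origin-adjusted (for ICI cohorts, from therapy start); the
loaders accept only CR/PR/SD/PD.

## Statistics

- **Fisher's exact test** (via scipy) uses the minimum-likelihood
  two-sided convention — the p-value sums hypergeometric probabilities of
  all same-margin tables no more likely than the observed one. This is
  the convention of mainstream statistical environments (R's
  `fisher.test`); two-sided Fisher has competing definitions, so the test
  suite pins this one against an exhaustive enumeration oracle for every
  table with total ≤ 40. A zero margin yields p = 1 with a degenerate
  flag instead of an exception. The odds ratio reported is the sample
  (unconditional) `ad/bc`, infinite when `bc = 0 < ad`.
- **Wilcoxon rank-sum** (via scipy) uses exact enumeration when both
  groups have ≤ 25 observations and the pooled values are tie-free, and
  otherwise the normal approximation with tie-corrected variance and a
  0.5 continuity correction. The crossover at 25 balances exactness
  against enumeration cost.
- **Kaplan–Meier / log-rank / Cox** go through lifelines. Ties are
  handled with Efron's correction — months-resolution data guarantee
  ties, and Efron is the default of the survival software this kind of
  analysis is normally run with. The Newton–Raphson precision is
  tightened to 1e-9 so coefficients agree with a brute-force
  partial-likelihood grid search to 1e-4 (tested). Median survival is
  the smallest observed time with S(t) ≤ 0.5 and is reported as "not
  reached" (never a number) while the curve stays above 0.5. Covariates
  with runaway coefficients (|β| > 10) raise a monotone-likelihood
  (complete separation) error naming the covariate; categorical
  covariates are one-hot encoded against the alphabetically first level
  so designs are deterministic.
- **Harrell's C-index** is implemented in-module: a pair is usable iff
  the strictly smaller time is an event; tied risk scores count 1/2;
  higher risk must predict shorter survival. Equal-time pairs are
  excluded entirely (some implementations count death-vs-censored ties
  at the same time; the stricter rule is used here and pinned by a
  pair-enumeration oracle test). The orientation of a raw binary marker
  is the caller's explicit choice — protective markers enter as
  `1 − indicator` — with no silent `max(c, 1−c)` folding.
- **Resampling stability** draws, per iteration, a wildtype subsample of
  the mutant arm's size without replacement, then records the WT
  subsample's KM median and the mutant-vs-subsample Cox HR. Aggregates
  are means plus **empirical 2.5–97.5 percentile intervals**, labelled as
  such (a normal-theory interval would be an alternative; percentiles
  make no shape assumption). Iterations with no events or a
  non-convergent fit contribute missing values, which are counted and
  reported.

## Immune scoring

- **ssGSEA**: per sample, genes are ranked by expression (average ranks
  on ties); walking the list in descending order, the score is
  `Σ_i [ECDF_in^w(i) − ECDF_out(i)]` where the in-set ECDF weights gene
  ranks by `rank^α` with α = 0.25 and the out-of-set ECDF is uniform.
  Optional normalization divides all scores by the global max − min
  across samples and sets. Because only ranks enter, scores are
  invariant to any strictly increasing per-sample transform (tested).
  Within a tie block the walk order is the matrix's gene order (stable
  sort), which is deterministic; tied genes share a weight, so the
  choice only affects the partial sums inside the block.
- **MCP-style scores**: arithmetic mean of log2(x+1) marker expression
  per population. **CYT**: geometric mean of GZMA and PRF1 on the linear
  scale with a 0.01 pseudocount (the customary guard against zero
  products; the exact value is a convention). **Pathway score**: mean
  log2(x+1) of activated genes minus mean of repressed genes.
  Expression matrices carry an explicit scale tag (`linear` /
  `log2p1`); conversions follow the tag and are never guessed. Missing
  genes are dropped with recorded coverage, never imputed.
- **Lymphocyte fraction** sums 12 of the 22 CIBERSORT categories
  (plasma cells; activated and resting NK; CD8; γδ; Tregs; follicular
  helper; naïve, memory-resting and memory-activated CD4; naïve and
  memory B), so uniform proportions give 12/22. **TIL fraction** is the
  product of the methylation-derived leukocyte fraction and the
  lymphocyte fraction, bounded by both factors. CIBERSORT proportions
  are consumed as inputs (relative-fraction convention, sum 1 within
  1e-6); no deconvolution is performed here.
- The bundled 29-signature, MCP-marker and NOTCH-pathway (50 activated /
  21 repressed) GMT files are **synthetic stand-ins**: the curated
  collections are published separately and gene content is a
  configuration concern, so any GMT file can be supplied instead.

## Synthetic cohort

Defaults describe a discovery-style ICI cohort of 662 patients:

| parameter | default | meaning |
|---|---|---|
| `n_mut`, `n_wt` | 63, 599 | arm sizes |
| `response_probs_mut` | (.101, .328, .222, .349) | P(CR, PR, SD, PD); CR∪PR = .429 |
| `response_probs_wt` | (.061, .198, .245, .496) | CR∪PR = .259 |
| `p_sd_durable` | 0.5 | P(SD duration > 6 mo); SD ~ Exp, rate −ln(.5)/6 |
| `pfs_hazard_wt`, `os_hazard_wt` | ln2/3.6, ln2/17.8 per mo | WT medians 3.6 / 17.8 mo |
| `hr_pfs`, `hr_os` | 0.558, 0.568 | mutant-vs-wildtype hazard ratios |
| `censor_hazard` | 0.03 per mo | independent exponential censoring (~10–20% censored for PFS) |
| `weibull_shape` | 1.0 | event-time shape; 1 = exponential (constant HR either way) |
| `background_mutation_rate_mut/wt` | 380 / 190 | mean nonsyn variants/sample (WES TMB ≈ 10 vs 5 mut/Mb) |
| `immune_effect` | 1.0 | additive log2 shift of immune marker genes in mutant samples |

The response-probability vectors are derived from the arm-level ORR and
DCB rates plus the cohort-level CR:PR and SD shares; with
`p_sd_durable = 0.5` they reproduce DCB ≈ 54% / 38% in expectation.
Event times are exponential by default — the simplest model consistent
with a constant hazard ratio (a Weibull shape is exposed but not
default). PFS and OS are drawn independently, and response category is
linked to survival only through arm membership: no joint model of
response and progression is attempted, which is a deliberate
simplification. Mutation tables mix the six nonsynonymous classes with
a ~35% admixture of silent/in-frame rows so the filter is exercised;
every mutant sample carries ≥ 1 query-gene nonsynonymous variant and no
wildtype sample carries any, so stratification recovers the truth
labels exactly (tested). Expression is Gaussian on the log2 scale with
immune marker genes shifted by `immune_effect` in mutants; cell
fractions are Dirichlet with lymphoid components up-weighted by
`exp(0.4 · immune_effect)` in mutants; the leukocyte fraction is Beta
with a mutant-shifted first parameter.

One global seed feeds fixed-offset substreams per data section (arms,
responses, SD durations, PFS, OS, mutations, expression, fractions,
covariates), so enlarging the gene universe never perturbs the clinical
draws and identical config + seed is byte-identical on disk.

What the generator does **not** emulate: mutational signatures and
gene–gene linkage, tumor purity, joint response–survival dependence,
informative censoring, between-cohort batch structure, and realistic
covariance between expression programs. Passing tests therefore
demonstrate correctness of the estimators and the pipeline's contracts
under a known truth — not that any particular real-world cohort will
show these effect sizes.

## Reporting and determinism

Pipeline reports are pure functions of (inputs, config, seed): artifact
hashes are stable across reruns, timestamps go only to logs, and every
random draw traces to the config seed. Problem sizes used by the
acceptance recomputation — 100 cohorts for hazard-ratio recovery, 200
for log-rank calibration, 1000 resampling iterations — were chosen as
the smallest sizes at which the Monte-Carlo error is comfortably below
the quantities' tolerances.

## Known limitations

- The Cox machinery covers fixed covariates only: no time-varying
  effects, proportional-hazards diagnostics, or restricted-mean
  summaries.
- No multiple-testing correction is applied to the per-feature immune
  contrasts; the comparison table is ordered by raw p.
- Gene symbols are matched textually; cohorts annotated with different
  symbol vintages need harmonizing upstream.
- C-index values on small marker-complete subsets are noisy; the
  reported subset size should temper interpretation.
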