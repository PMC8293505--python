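# icibench

Evaluation pipeline for **mutation biomarkers of immune-checkpoint-inhibitor
(ICI) response**. Given a somatic mutation table, a clinical outcome table
and (optionally) bulk expression and immune-cell-fraction data, the package
stratifies a cohort by a query gene's nonsynonymous mutation status and
quantifies whether mutant patients do better on checkpoint blockade:

- **Response / benefit** — objective response rate (ORR: RECIST best
  response CR or PR) and durable clinical benefit (DCB: CR/PR, or SD
  lasting > 6 months) per arm, with two-sided Fisher's exact tests on the
  2×2 arm × outcome tables.
- **Survival** — Kaplan–Meier medians, the Mantel–Cox log-rank test, and
  Cox proportional-hazards models (Efron ties, Wald 95% CIs), univariate
  and adjusted for cancer type; the hazard ratio `HR = exp(β)` indexes the
  mutant arm, so HR < 1 favors mutant patients.
- **Stability** — the arms are usually badly unbalanced (e.g. 63 vs 599),
  so the wildtype arm is repeatedly downsampled to the mutant arm's size
  (1000 samplings) and the per-iteration WT median PFS and Cox HR are
  summarized with empirical 2.5–97.5 percentile intervals.
- **Marker comparison** — Harrell's C-index of candidate risk markers
  (mutation status, median-dichotomized TMB, PD-L1 positivity) on their
  common sample subset.
- **Immune landscape** — TMB (nonsynonymous mutations / Mb, normalized by
  assay footprint: 38 Mb for WES, 1.22/1.06/0.98 Mb for the 468/410/341-gene
  panels), ssGSEA enrichment of immune signatures, MCP-style population
  scores, cytolytic activity `CYT = sqrt(GZMA · PRF1)`, a NOTCH-pathway
  score (mean activated minus mean repressed expression), and
  lymphocyte/TIL fractions — each contrasted between arms with the
  Wilcoxon rank-sum test.

A synthetic-cohort generator (`icibench.simulate`) reproduces the
statistical structure of a discovery-style ICI cohort (two arms with
arm-specific response probabilities, exponential PFS/OS with a set hazard
ratio under independent censoring, higher mutant-arm mutation load,
immune-shifted expression), so the whole pipeline is testable offline;
real cohorts in the same TSV/MAF/GMT formats drop straight in.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
662-patient cohort (63 mutant / 599 wildtype, generating PFS hazard ratio
0.558):

```sh
python analysis/01_simulate_cohort.py --seed 7
python analysis/02_clinical_benefit.py
python analysis/03_survival_analysis.py
python analysis/04_resampling_stability.py
python analysis/05_immune_landscape.py
```

which prints, among other things:

```
ORR: 42.9% (mutant) vs 24.5% (wildtype), Fisher p = 0.0025
DCB: 54.0% (mutant) vs 35.2% (wildtype), Fisher p = 0.0057
TMB: median 10.03 vs 5.00 mut/Mb, Wilcoxon p = 4.87e-39
PFS: median 9.6 vs 3.4 months; HR = 0.414 [0.302, 0.567], log-rank p = 1.57e-08
full-cohort HR = 0.414
1000 samplings of 63 wildtype patients:
  mean WT median PFS = 3.383 months [2.297, 4.702] (empirical 2.5-97.5 pct)
  mean HR = 0.401 [0.300, 0.522]
43 features compared; 41 enriched in the mutant arm at p < 0.05
```

Read: in this cohort realization the mutant arm responds more often
(42.9% vs 24.5%), progresses later (median PFS 9.6 vs 3.4 months, HR
0.414 — a single-seed draw around the generating 0.558), and the
advantage survives 1000 wildtype downsamplings (mean HR 0.401, interval
entirely below 1). The immune contrast finds the signatures that the
generator shifted upward in mutant tumors. Tables land in `results/`.

The same stages are available as a CLI (`icibench simulate | stratify |
associate | survival | resample | immune-score | run`) and as a single
orchestrated run from a YAML config (`icibench run --config ...`), which
writes a deterministic JSON report whose hash depends only on inputs,
config and seed.

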