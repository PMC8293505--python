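#!/usr/bin/env python
"""Survival contrast: KM medians, log-rank, Cox models and C-indices.

Fits per-arm Kaplan-Meier curves for PFS and OS, the Mantel-Cox
log-rank test, univariate and cancer-type-adjusted Cox models, and
compares candidate markers (mutation status, dichotomized TMB, PD-L1)
by Harrell's C-index on their common sample subset.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from icibench import clinical as clin
from icibench import mutations as mut
from icibench import survival as sv
from icibench.pipeline import compare_markers, dichotomize_at_median

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--gene", default="NOTCH4")
parser.add_argument("--out", type=Path, default=Path("results/survival.json"))
args = parser.parse_args()

manifest = [l for l in (args.cohort / "manifest.txt").read_text().splitlines() if l]
records = mut.filter_nonsynonymous(mut.read_maf(args.cohort / "mutations.maf.tsv", manifest))
status = mut.call_gene_status(records, manifest, args.gene)
frame = clin.clinical_to_frame(clin.read_clinical_table(args.cohort / "clinical.tsv"))
tmb = mut.compute_tmb(records, manifest)
merged = frame.join(status["status"])
merged["mutant"] = (merged["status"] == "MUT").astype(float)

out = {}
for ep in ("pfs", "os"):
    tcol, ecol = f"{ep}_months", f"{ep}_event"
    m, w = merged[merged["mutant"] == 1], merged[merged["mutant"] == 0]
    km_m, km_w = sv.km_fit(m[tcol], m[ecol]), sv.km_fit(w[tcol], w[ecol])
    lr = sv.logrank_test(m[tcol], m[ecol], w[tcol], w[ecol])
    uni = sv.cox_fit(merged[[tcol, ecol, "mutant"]], tcol, ecol, ["mutant"])
    design = sv.build_design(merged, "mutant", ["cancer_type"])
    multi = sv.cox_fit(pd.concat([merged[[tcol, ecol]], design], axis=1),
                       tcol, ecol, list(design.columns))
    row = uni.summary.loc["mutant"]
    mrow = multi.summary.loc["mutant"]
    out[ep] = {
        "median_mut": km_m.median if km_m.median is not None else "not reached",
        "median_wt": km_w.median if km_w.median is not None else "not reached",
        "logrank_p": lr.p_value,
        "hr_univariate": row["hr"], "ci": [row["ci_lower"], row["ci_upper"]],
        "hr_adjusted": mrow["hr"], "ci_adjusted": [mrow["ci_lower"], mrow["ci_upper"]],
    }
    print(f"{ep.upper()}: median {out[ep]['median_mut']} vs {out[ep]['median_wt']} months; "
          f"HR = {row['hr']:.3f} [{row['ci_lower']:.3f}, {row['ci_upper']:.3f}], "
          f"log-rank p = {lr.p_value:.2e}; adjusted HR = {mrow['hr']:.3f}")

pdl1 = frame["pdl1_status"]
markers = {
    args.gene: 1.0 - merged["mutant"],
    "TMB_high": 1.0 - dichotomize_at_median(tmb).astype(float),
    "PDL1_positive": (1.0 - (pdl1 == "positive").astype(float)).where(
        pdl1.isin(["positive", "negative"])),
}
cmp_table = compare_markers(merged, markers, endpoint="os")
out["c_index"] = cmp_table.to_dict(orient="index")
print("C-index (OS, common subset of "
      f"{int(cmp_table['n'].iloc[0])} patients):")
for marker, row in cmp_table.iterrows():
    print(f"  {marker}: {row['c_index']:.3f}")

args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(out, indent=2))
print(f"wrote {args.out}")
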