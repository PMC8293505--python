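#!/usr/bin/env python
"""Response and durable-benefit contrast between the mutation arms.

Stratifies the simulated cohort by nonsynonymous mutation status, builds
the ORR and DCB contingency tables with two-sided Fisher tests, and
contrasts TMB between arms.  Tables are written to results/.
"""

import argparse
import json
from pathlib import Path

from icibench import clinical as clin
from icibench import mutations as mut
from icibench.stats import fisher_exact, wilcoxon_rank_sum

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--gene", default="NOTCH4")
parser.add_argument("--out", type=Path, default=Path("results/clinical_benefit.json"))
args = parser.parse_args()

manifest = [l for l in (args.cohort / "manifest.txt").read_text().splitlines() if l]
records = mut.filter_nonsynonymous(mut.read_maf(args.cohort / "mutations.maf.tsv", manifest))
status = mut.call_gene_status(records, manifest, args.gene)
clinical = clin.read_clinical_table(args.cohort / "clinical.tsv")
tmb = mut.compute_tmb(records, manifest)

out = {}
for endpoint in ("ORR", "DCB"):
    table, rate_mut, rate_wt = clin.build_benefit_table(clinical, status, endpoint)
    fisher = fisher_exact(table)
    out[endpoint] = {"table": [[table.a, table.b], [table.c, table.d]],
                     "rate_mut_pct": rate_mut, "rate_wt_pct": rate_wt,
                     "fisher_p": fisher.p_value, "odds_ratio": table.odds_ratio}
    print(f"{endpoint}: {rate_mut}% (mutant) vs {rate_wt}% (wildtype), "
          f"Fisher p = {fisher.p_value:.4f}")

arm = status["status"]
wtest = wilcoxon_rank_sum(tmb[arm == "MUT"], tmb[arm == "WT"])
out["TMB"] = {"median_mut": float(tmb[arm == "MUT"].median()),
              "median_wt": float(tmb[arm == "WT"].median()),
              "wilcoxon_p": wtest.p_value}
print(f"TMB: median {out['TMB']['median_mut']:.2f} vs {out['TMB']['median_wt']:.2f} mut/Mb, "
      f"Wilcoxon p = {wtest.p_value:.2e}")

args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(out, indent=2))
print(f"wrote {args.out}")
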