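#!/usr/bin/env python
"""Immune-landscape contrast between the mutation arms.

Scores the expression matrix with ssGSEA (29 signatures), MCP-style
population means, cytolytic activity and the NOTCH-pathway score, adds
the lymphocyte/TIL fractions from the cell-fraction table, and tests
each feature between arms with the Wilcoxon rank-sum test.  The ordered
(volcano-ready) comparison table goes to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from icibench import immune as imm
from icibench import mutations as mut
from icibench.simulate import (
    default_mcp_collection,
    default_notch_pathway,
    default_signature_collection,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--gene", default="NOTCH4")
parser.add_argument("--out", type=Path, default=Path("results/immune_comparison.tsv"))
args = parser.parse_args()

manifest = [l for l in (args.cohort / "manifest.txt").read_text().splitlines() if l]
records = mut.filter_nonsynonymous(mut.read_maf(args.cohort / "mutations.maf.tsv", manifest))
status = mut.call_gene_status(records, manifest, args.gene)
expr = imm.ExpressionMatrix.read_tsv(args.cohort / "expression.tsv", scale="log2p1")
fractions = pd.read_csv(args.cohort / "cell_fractions.tsv", sep="\t", index_col=0)

notch = default_notch_pathway()
act = next(n for n in notch if notch.directions[n] == "activated")
rep = next(n for n in notch if notch.directions[n] == "repressed")

blocks = {
    "ssgsea": imm.ssgsea(expr, default_signature_collection(), normalize=True).scores,
    "mcp": imm.mcp_scores(expr, default_mcp_collection()).scores,
    "single": pd.DataFrame({
        "CYT": imm.cyt_score(expr),
        "NOTCH_pathway_score": imm.pathway_score(expr, notch[act], notch[rep]),
        "lymphocyte_fraction": imm.lymphocyte_fraction(
            fractions[list(imm.CIBERSORT_CATEGORIES)]),
        "til_fraction": imm.til_fraction(
            fractions["leukocyte_fraction"],
            imm.lymphocyte_fraction(fractions[list(imm.CIBERSORT_CATEGORIES)])),
    }).T,
}

tables = []
for method, scores in blocks.items():
    table = imm.compare_by_arm(scores, status)
    table.insert(0, "method", method)
    tables.append(table)
combined = pd.concat(tables).sort_values("p", kind="stable")

n_enriched = ((combined["p"] < 0.05) & (combined["direction"] == "MUT")).sum()
print(f"{len(combined)} features compared; "
      f"{n_enriched} enriched in the mutant arm at p < 0.05")
print("top features:")
print(combined.head(8)[["method", "p", "median_mut", "median_wt", "direction"]]
      .to_string(float_format=lambda v: f"{v:.3g}"))

args.out.parent.mkdir(parents=True, exist_ok=True)
combined.to_csv(args.out, sep="\t")
print(f"wrote {args.out}")
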