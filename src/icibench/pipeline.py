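"""End-to-end discovery-style analysis over one cohort.

Runs the full evaluation of a mutation biomarker in an immunotherapy
cohort: stratification by nonsynonymous mutation status, TMB, ORR/DCB
contingency tables with Fisher tests, Kaplan-Meier / log-rank / Cox
survival (univariate and cancer-type-adjusted), C-index comparison of
candidate markers, wildtype-downsampling stability, and — when
expression and cell-fraction inputs are supplied — the immune-landscape
contrasts (ssGSEA signatures, MCP populations, CYT, NOTCH-pathway
score, lymphocyte/TIL fractions).

Reports are reproducible: every number is a pure function of the input
files, the configuration and the seed, and ``report_hash`` certifies it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import immune as imm
from . import mutations as mut
from . import survival as surv
from .simulate import (
    default_mcp_collection,
    default_notch_pathway,
    default_signature_collection,
)
from .stats import fisher_exact, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_pipeline", "compare_markers",
           "dichotomize_at_median"]

#: strata smaller than this are not analysed separately
SUBGROUP_MIN_N = 50
#: markers missing in more than this fraction of samples are dropped
MARKER_MAX_MISSING = 0.5


@dataclass
class AnalysisConfig:
    """Paths and knobs for one pipeline run."""

    maf: str
    manifest: str
    clinical: str
    query_gene: str = "NOTCH4"
    expression: Optional[str] = None
    expression_scale: str = "log2p1"
    cell_fractions: Optional[str] = None
    signatures_gmt: Optional[str] = None
    mcp_gmt: Optional[str] = None
    pathway_gmt: Optional[str] = None
    gene_family: tuple = mut.NOTCH_FAMILY
    repair_genes: tuple = mut.HOMOLOGOUS_REPAIR_GENES
    endpoints: tuple = ("pfs", "os")
    resampling_iterations: int = 1000
    seed: int = 0
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("maf", "manifest", "clinical", "expression", "cell_fractions",
                     "signatures_gmt", "mcp_gmt", "pathway_gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for ep in self.endpoints:
            if ep not in ("pfs", "os"):
                raise ValueError(f"unknown endpoint {ep!r}")
        if self.resampling_iterations < 1:
            raise ValueError("resampling_iterations must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Structured result of one pipeline run."""

    sections: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"sections": self.sections, "provenance": self.provenance},
            sort_keys=True, indent=2, default=_jsonify,
        )

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def dichotomize_at_median(values: pd.Series) -> pd.Series:
    """High/low split: 1 for values strictly greater than the median."""
    return (values > values.median()).astype(int)


def _test_result_dict(res) -> dict:
    return {"statistic": res.statistic, "p": res.p_value, "method": res.method,
            "degenerate": res.degenerate}


def _benefit_section(table, rate_mut, rate_wt) -> dict:
    fisher = fisher_exact(table)
    return {
        "table": [[table.a, table.b], [table.c, table.d]],
        "rate_mut_pct": rate_mut,
        "rate_wt_pct": rate_wt,
        "odds_ratio": table.odds_ratio,
        "fisher": _test_result_dict(fisher),
    }


def _km_dict(curve: surv.KMCurve) -> dict:
    return {"median": curve.median if curve.median is not None else "not reached",
            "n_events": int(curve.n_events.sum())}


def _survival_section(frame: pd.DataFrame, status: pd.DataFrame, endpoint: str,
                      adjust_cancer_type: bool = True) -> dict:
    time_col, event_col = f"{endpoint}_months", f"{endpoint}_event"
    merged = frame.join(status["status"])
    mut_arm = merged[merged["status"] == "MUT"]
    wt_arm = merged[merged["status"] == "WT"]
    km_mut = surv.km_fit(mut_arm[time_col], mut_arm[event_col])
    km_wt = surv.km_fit(wt_arm[time_col], wt_arm[event_col])
    lr = surv.logrank_test(mut_arm[time_col], mut_arm[event_col],
                           wt_arm[time_col], wt_arm[event_col])
    merged["mutant"] = (merged["status"] == "MUT").astype(float)
    uni = surv.cox_fit(
        pd.concat([merged[[time_col, event_col]], merged[["mutant"]]], axis=1),
        time_col, event_col, ["mutant"])
    section = {
        "km_mut": _km_dict(km_mut),
        "km_wt": _km_dict(km_wt),
        "logrank": _test_result_dict(lr),
        "cox_univariate": uni.summary.to_dict(orient="index"),
    }
    if adjust_cancer_type and merged["cancer_type"].nunique() > 1:
        design = surv.build_design(merged, "mutant", ["cancer_type"])
        multi = surv.cox_fit(
            pd.concat([merged[[time_col, event_col]], design], axis=1),
            time_col, event_col, list(design.columns))
        section["cox_multivariate"] = multi.summary.to_dict(orient="index")
    # per-cancer-type subgroups, only for adequately sized strata
    subgroups = {}
    for ct, sub in merged.groupby("cancer_type"):
        if len(sub) < SUBGROUP_MIN_N or sub["mutant"].nunique() < 2:
            continue
        if sub[event_col].sum() < 1:
            continue
        try:
            fit = surv.cox_fit(sub[[time_col, event_col, "mutant"]],
                               time_col, event_col, ["mutant"])
            subgroups[ct] = {"n": int(len(sub)), "hr": fit.hr("mutant")}
        except (RuntimeError, ValueError):
            subgroups[ct] = {"n": int(len(sub)), "hr": None}
    section["subgroups"] = subgroups
    return section


def compare_markers(frame: pd.DataFrame, markers: dict[str, pd.Series],
                    endpoint: str = "os") -> pd.DataFrame:
    """Harrell's C-index of each candidate risk score on a common subset.

    ``markers`` maps a name to a per-sample *risk* score (higher = worse
    expected survival; the caller fixes the orientation, e.g. ``1 -
    mutant`` for a protective binary marker).  Markers undefined in more
    than half the samples are excluded with a warning; the C-index is
    computed on the intersection of samples where every retained marker
    is defined, and that sample count is reported per row.
    """
    time_col, event_col = f"{endpoint}_months", f"{endpoint}_event"
    kept = {}
    for name, score in markers.items():
        score = score.reindex(frame.index)
        frac_missing = score.isna().mean()
        if frac_missing > MARKER_MAX_MISSING:
            logger.warning("marker %s missing in %.0f%% of samples; excluded",
                           name, 100 * frac_missing)
            continue
        kept[name] = score
    if not kept:
        raise ValueError("no marker defined on enough samples")
    common = frame.index
    for score in kept.values():
        common = common[score.reindex(common).notna()]
    rows = []
    for name, score in kept.items():
        c = surv.c_index(frame.loc[common, time_col], frame.loc[common, event_col],
                         score.loc[common])
        rows.append({"marker": name, "c_index": c, "n": int(len(common))})
    return pd.DataFrame(rows).set_index("marker")


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute every stage on the configured inputs and return the report.

    Stage order: stratification -> TMB -> outcome tables -> association
    tests -> survival -> C-index -> resampling -> immune scoring.  The
    immune sections are marked ``skipped`` when no expression /
    cell-fraction inputs are configured.  Re-running with identical
    inputs, config and seed reproduces the report byte for byte.
    """
    config.validate()
    manifest = [line.strip() for line in Path(config.manifest).read_text().splitlines()
                if line.strip()]
    clinical = clin.read_clinical_table(config.clinical)
    clin_ids = {r.sample_id for r in clinical}
    if clin_ids != set(manifest):
        raise ValueError(
            "clinical and manifest sample universes are inconsistent; "
            f"symmetric difference: {sorted(clin_ids ^ set(manifest))}"
        )
    frame = clin.clinical_to_frame(clinical)

    records = mut.read_maf(config.maf, manifest)
    nonsyn = mut.filter_nonsynonymous(records)
    status = mut.call_gene_status(nonsyn, manifest, config.query_gene)
    family_status = mut.call_geneset_status(nonsyn, manifest, config.gene_family)
    repair_status = mut.call_geneset_status(nonsyn, manifest, config.repair_genes)
    tmb = mut.compute_tmb(nonsyn, manifest)

    report = AnalysisReport()
    report.sections["cohort"] = {
        "n": len(manifest),
        "n_mut": int((status["status"] == "MUT").sum()),
        "n_wt": int((status["status"] == "WT").sum()),
        "query_gene": config.query_gene,
        "best_response_counts": frame["best_response"].value_counts().to_dict(),
        "cancer_type_counts": frame["cancer_type"].value_counts().to_dict(),
        "drug_class_counts": frame["drug_class"].value_counts().to_dict(),
    }

    # --- response / benefit ------------------------------------------
    for endpoint in ("ORR", "DCB"):
        table, rate_mut, rate_wt = clin.build_benefit_table(clinical, status, endpoint)
        report.sections[endpoint.lower()] = _benefit_section(table, rate_mut, rate_wt)

    # --- co-occurrence with the repair pathway and family status ------
    co = mut.cooccurrence_table(status, repair_status)
    report.sections["repair_cooccurrence"] = {
        "table": [[co.a, co.b], [co.c, co.d]],
        "fisher": _test_result_dict(fisher_exact(co)),
    }

    # --- TMB by arm ----------------------------------------------------
    tmb_mut = tmb[status["status"] == "MUT"]
    tmb_wt = tmb[status["status"] == "WT"]
    report.sections["tmb"] = {
        "median_mut": float(tmb_mut.median()),
        "median_wt": float(tmb_wt.median()),
        "wilcoxon": _test_result_dict(wilcoxon_rank_sum(tmb_mut, tmb_wt)),
    }

    # --- survival ------------------------------------------------------
    for ep in config.endpoints:
        report.sections[f"survival_{ep}"] = _survival_section(frame, status, ep)
        family_sec = _survival_section(frame, family_status, ep, adjust_cancer_type=False)
        report.sections[f"survival_{ep}_family"] = {
            "km_altered": family_sec["km_mut"],
            "km_unaltered": family_sec["km_wt"],
            "logrank": family_sec["logrank"],
            "cox_univariate": family_sec["cox_univariate"],
        }

    # --- C-index marker comparison ------------------------------------
    markers = {
        # protective markers enter as 1 - indicator so higher = riskier
        config.query_gene: 1.0 - (status["status"] == "MUT").astype(float),
        "TMB_high": 1.0 - dichotomize_at_median(tmb).astype(float),
    }
    pdl1 = frame["pdl1_status"]
    defined = pdl1.isin(["positive", "negative"])
    markers["PDL1_positive"] = (1.0 - (pdl1 == "positive").astype(float)).where(defined)
    endpoint = "os" if "os" in config.endpoints else config.endpoints[0]
    try:
        cmp_table = compare_markers(frame, markers, endpoint)
        report.sections["c_index"] = cmp_table.to_dict(orient="index")
    except ValueError as err:
        report.sections["c_index"] = {"skipped": str(err)}

    # --- resampling stability (PFS) ------------------------------------
    sdf = pd.DataFrame({"time": frame["pfs_months"], "event": frame["pfs_event"]})
    mut_arm = sdf[status["status"] == "MUT"]
    wt_arm = sdf[status["status"] == "WT"]
    rs = surv.resample_stability(mut_arm, wt_arm, n_iter=config.resampling_iterations,
                                 seed=config.seed)
    report.sections["resampling"] = {
        "n_iterations": rs.n_iterations,
        "mean_wt_median_pfs": rs.mean_wt_median,
        "ci_wt_median_pfs": list(rs.ci_wt_median),
        "mean_hr": rs.mean_hr,
        "ci_hr": list(rs.ci_hr),
        "n_missing_median": rs.n_missing_median,
        "n_missing_hr": rs.n_missing_hr,
    }

    # --- immune landscape ----------------------------------------------
    if config.expression is not None:
        expr = imm.ExpressionMatrix.read_tsv(config.expression, scale=config.expression_scale)
        sigs = (imm.read_gmt(config.signatures_gmt) if config.signatures_gmt
                else default_signature_collection())
        mcp_sets = (imm.read_gmt(config.mcp_gmt) if config.mcp_gmt
                    else default_mcp_collection())
        pathway = (imm.read_gmt(config.pathway_gmt) if config.pathway_gmt
                   else default_notch_pathway())
        act = next(n for n in pathway if pathway.directions.get(n) == "activated")
        rep = next(n for n in pathway if pathway.directions.get(n) == "repressed")

        sig_scores = imm.ssgsea(expr, sigs, normalize=True)
        report.sections["ssgsea"] = {
            "comparison": imm.compare_by_arm(sig_scores.scores, status).to_dict(orient="index"),
            "errors": sig_scores.errors,
        }
        mcp = imm.mcp_scores(expr, mcp_sets)
        report.sections["mcp"] = {
            "comparison": imm.compare_by_arm(mcp.scores, status).to_dict(orient="index"),
            "errors": mcp.errors,
        }
        cyt = imm.cyt_score(expr)
        path_score = imm.pathway_score(expr, pathway[act], pathway[rep])
        single = pd.DataFrame({"CYT": cyt, "NOTCH_pathway_score": path_score}).T
        report.sections["expression_scores"] = {
            "comparison": imm.compare_by_arm(single, status).to_dict(orient="index"),
        }
    else:
        for key in ("ssgsea", "mcp", "expression_scores"):
            report.sections[key] = "skipped"

    if config.cell_fractions is not None:
        fr = pd.read_csv(config.cell_fractions, sep="\t", index_col=0)
        leuk = fr["leukocyte_fraction"]
        lymph = imm.lymphocyte_fraction(fr)
        til = imm.til_fraction(leuk, lymph)
        fraction_scores = pd.DataFrame(
            {"leukocyte_fraction": leuk, "lymphocyte_fraction": lymph, "til_fraction": til}
        ).T
        report.sections["fractions"] = {
            "comparison": imm.compare_by_arm(fraction_scores, status).to_dict(orient="index"),
        }
    else:
        report.sections["fractions"] = "skipped"

    report.provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                         "query_gene": config.query_gene}

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json())
        status.to_csv(outdir / "gene_status.tsv", sep="\t")
        tmb.rename("tmb").to_frame().to_csv(outdir / "tmb.tsv", sep="\t")
    return report
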