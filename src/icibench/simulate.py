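"""Synthetic two-arm immunotherapy cohort generator.

Every downstream stage of the pipeline (stratification, clinical
benefit, survival, immune scoring) is exercised offline against data
from this module.  The generator emulates the statistical structure of a
discovery-style immunotherapy cohort: a small mutant arm and a large
wildtype arm (63 / 599 by default), arm-specific RECIST response
probabilities (objective response 42.9% vs 25.9%), stable-disease
durations straddling the 6-month durable-benefit boundary, exponential
progression-free and overall survival with a configurable mutant-vs-
wildtype hazard ratio (0.558 / 0.568 by default, baseline hazards set
so the wildtype medians are 3.6 and 17.8 months) under independent
exponential censoring, a higher nonsynonymous mutation load in the
mutant arm, and an expression matrix whose immune marker genes are
shifted upward in mutant samples.

The defaults *are* the study conditions; deviations for experiments are
the caller's explicit choice.  A fixed seed yields byte-identical
output: each data section draws from its own substream derived from the
global seed by a fixed offset, so e.g. enlarging the gene universe never
perturbs the clinical draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord
from .immune import (
    CIBERSORT_CATEGORIES,
    LYMPHOCYTE_CATEGORIES,
    ExpressionMatrix,
    GeneSetCollection,
    read_gmt,
)
from .mutations import NONSYNONYMOUS_CLASSES

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "default_signature_collection",
    "default_mcp_collection",
    "default_notch_pathway",
]

_RESPONSES = ("CR", "PR", "SD", "PD")

# substream offsets; fixed so sections never share draws
_SS_ARMS, _SS_RESPONSE, _SS_SDDUR, _SS_PFS, _SS_OS = 0, 1, 2, 3, 4
_SS_MUTATIONS, _SS_EXPRESSION, _SS_FRACTIONS, _SS_COVARIATES = 5, 6, 7, 8

_CANCER_TYPE_PROBS = {
    "NSCLC": 296 / 662,
    "Melanoma": 287 / 662,
    "Esophagogastric": 40 / 662,
    "Bladder": 27 / 662,
    "HNSCC": 12 / 662,
}
_P_COMBINATION = 54 / 662

# nonsynonymous class frequencies for simulated variant rows, plus a
# fringe of non-qualifying classes so the filter has something to drop
_NONSYN_CLASS_PROBS = {
    "Missense_Mutation": 0.70,
    "Nonsense_Mutation": 0.12,
    "Frame_Shift_Del": 0.07,
    "Frame_Shift_Ins": 0.05,
    "Splice_Site": 0.04,
    "Translation_Start_Site": 0.01,
    "Nonstop_Mutation": 0.01,
}
_SILENT_CLASS_PROBS = {"Silent": 0.7, "In_Frame_Del": 0.15, "In_Frame_Ins": 0.15}
_SILENT_PER_NONSYN = 0.35  # synonymous-ish rows generated per nonsynonymous row


def _data_path(name: str):
    return resources.files("icibench.data") / name


def default_signature_collection() -> GeneSetCollection:
    """The bundled 29-signature collection (synthetic gene content)."""
    return read_gmt(_data_path("synthetic_immune_signatures.gmt"))


def default_mcp_collection() -> GeneSetCollection:
    """The bundled 10-population MCP marker collection (synthetic)."""
    return read_gmt(_data_path("synthetic_mcp_markers.gmt"))


def default_notch_pathway() -> GeneSetCollection:
    """Bundled NOTCH-pathway sets: 50 activated / 21 repressed genes.

    Synthetic stand-in content; the real curated lists are a
    configuration concern and can be swapped in as a GMT file.
    """
    return read_gmt(_data_path("synthetic_notch_pathway.gmt"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults emulate the
    discovery-style study conditions described in the module docstring."""

    n_mut: int = 63
    n_wt: int = 599
    # P(CR), P(PR), P(SD), P(PD); CR+PR = 0.429 (mutant) / 0.259 (wildtype)
    response_probs_mut: tuple = (0.101, 0.328, 0.222, 0.349)
    response_probs_wt: tuple = (0.061, 0.198, 0.245, 0.496)
    p_sd_durable: float = 0.5  # P(SD duration > 6 months)
    pfs_hazard_wt: float = math.log(2) / 3.6  # per month; WT median 3.6 mo
    os_hazard_wt: float = math.log(2) / 17.8  # per month; WT median 17.8 mo
    hr_pfs: float = 0.558
    hr_os: float = 0.568
    censor_hazard: float = 0.03  # per month, independent
    weibull_shape: float = 1.0  # 1.0 = exponential event times
    n_genes: int = 600
    immune_effect: float = 1.0  # additive log2 shift on immune markers, mutant arm
    assay: str = "WES"
    background_mutation_rate_mut: float = 380.0  # mean nonsyn variants/sample
    background_mutation_rate_wt: float = 190.0
    seed: int = 0

    def validate(self) -> None:
        for name, probs in (("response_probs_mut", self.response_probs_mut),
                            ("response_probs_wt", self.response_probs_wt)):
            probs = tuple(probs)
            if len(probs) != 4 or any(p < 0 for p in probs):
                raise ValueError(f"{name}: need 4 nonnegative probabilities, got {probs}")
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"{name}: probabilities sum to {sum(probs)!r}, not 1")
        if self.n_mut < 1 or self.n_wt < 1:
            raise ValueError("n_mut and n_wt must each be >= 1")
        if not (0.0 < self.p_sd_durable < 1.0):
            raise ValueError("p_sd_durable must lie strictly in (0, 1)")
        for name in ("pfs_hazard_wt", "os_hazard_wt", "hr_pfs", "hr_os",
                     "censor_hazard", "weibull_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.assay not in ("WES", "IMPACT468", "IMPACT410", "IMPACT341"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.background_mutation_rate_mut < self.background_mutation_rate_wt:
            raise ValueError(
                "background_mutation_rate_mut must be >= background_mutation_rate_wt"
            )
        if self.n_genes < 50:
            raise ValueError("n_genes must be >= 50")


@dataclass
class SyntheticCohort:
    """Generated cohort: mutation, clinical, expression and fraction data
    plus the ground truth that produced them."""

    mutations: pd.DataFrame
    manifest: list[str]
    clinical: list[ClinicalRecord]
    expression: ExpressionMatrix
    cell_fractions: pd.DataFrame  # samples x 22 categories
    leukocyte_fractions: pd.Series
    truth: dict  # {'config': ..., 'arm': {sample: 'MUT'|'WT'}}

    @property
    def arm(self) -> pd.Series:
        return pd.Series(self.truth["arm"], name="arm")


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([seed, offset])


def _gene_universe(n_genes: int) -> tuple[list[str], list[str]]:
    """Expression gene universe and the immune genes shifted in mutants."""
    sig = default_signature_collection()
    mcp = default_mcp_collection()
    notch = default_notch_pathway()
    immune = sorted({g for name in sig for g in sig[name]})
    stromal = sorted({g for name in ("Endothelial_cells", "Fibroblasts") for g in mcp[name]})
    pathway = sorted({g for name in notch for g in notch[name]})
    core = list(dict.fromkeys(immune + stromal + pathway + ["GZMA", "PRF1"]))
    fillers = [f"BG{i:04d}" for i in range(1, max(0, n_genes - len(core)) + 1)]
    return core + fillers, immune


def generate_cohort(config: SimulationConfig, query_gene: str = "NOTCH4") -> SyntheticCohort:
    """Draw a full synthetic cohort from ``config``.

    Stratifying the generated mutation table recovers the ground-truth
    arm labels exactly: every mutant sample carries at least one
    nonsynonymous variant of ``query_gene`` and no wildtype sample
    carries any.  Identical config + seed gives identical output.
    """
    config.validate()
    query_gene = query_gene.upper()
    n = config.n_mut + config.n_wt
    sample_ids = [f"P{i:04d}" for i in range(1, n + 1)]

    arm_flags = np.array([1] * config.n_mut + [0] * config.n_wt)
    _rng(config.seed, _SS_ARMS).shuffle(arm_flags)
    is_mut = arm_flags.astype(bool)
    arm = {s: ("MUT" if m else "WT") for s, m in zip(sample_ids, is_mut)}

    # --- responses and SD durations -----------------------------------
    rng_resp = _rng(config.seed, _SS_RESPONSE)
    u = rng_resp.random(n)
    cum_mut = np.cumsum(config.response_probs_mut)
    cum_wt = np.cumsum(config.response_probs_wt)
    resp_idx = np.where(is_mut, np.searchsorted(cum_mut, u, side="right"),
                        np.searchsorted(cum_wt, u, side="right")).clip(max=3)
    responses = [_RESPONSES[i] for i in resp_idx]
    # SD duration ~ Exp(rate) with P(>6) = p_sd_durable  =>  rate = -ln(p)/6
    sd_rate = -math.log(config.p_sd_durable) / 6.0
    sd_draws = _rng(config.seed, _SS_SDDUR).exponential(1.0 / sd_rate, size=n)

    # --- survival endpoints (independent PFS / OS) --------------------
    def endpoint(offset, base_hazard, hr):
        # WT cumulative hazard H(t) = (base_hazard * t)^shape; the mutant
        # arm multiplies H by hr, keeping the hazard ratio constant in t.
        rng_e = _rng(config.seed, offset)
        e = rng_e.exponential(1.0, size=n)
        e = np.where(is_mut, e / hr, e)
        t_event = e ** (1.0 / config.weibull_shape) / base_hazard
        t_cens = rng_e.exponential(1.0 / config.censor_hazard, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return np.maximum(np.round(time, 1), 0.1), event

    pfs_time, pfs_event = endpoint(_SS_PFS, config.pfs_hazard_wt, config.hr_pfs)
    os_time, os_event = endpoint(_SS_OS, config.os_hazard_wt, config.hr_os)

    # --- covariates ----------------------------------------------------
    rng_cov = _rng(config.seed, _SS_COVARIATES)
    ct_names = list(_CANCER_TYPE_PROBS)
    cancer_types = rng_cov.choice(ct_names, size=n, p=list(_CANCER_TYPE_PROBS.values()))
    drug = np.where(rng_cov.random(n) < _P_COMBINATION, "combination", "monotherapy")
    pdl1_u = rng_cov.random(n)
    pdl1 = np.where(pdl1_u < 0.45, "positive", np.where(pdl1_u < 0.80, "negative", "missing"))

    clinical = []
    for i, sid in enumerate(sample_ids):
        resp = responses[i]
        clinical.append(
            ClinicalRecord(
                sample_id=sid,
                best_response=resp,
                sd_duration_months=round(float(sd_draws[i]), 2) if resp == "SD" else None,
                pfs_months=float(pfs_time[i]),
                pfs_event=int(pfs_event[i]),
                os_months=float(os_time[i]),
                os_event=int(os_event[i]),
                cancer_type=str(cancer_types[i]),
                drug_class=str(drug[i]),
                pdl1_status=str(pdl1[i]),
            )
        )

    # --- mutation table -------------------------------------------------
    rng_mut = _rng(config.seed, _SS_MUTATIONS)
    bg_pool = np.array(
        [f"MUTG{i:04d}" for i in range(1, 301)]
        + [g for g in ("NOTCH1", "NOTCH2", "NOTCH3", "ATR", "ATM", "BRCA1", "BRCA2", "MUTYH")
           if g != query_gene]
    )
    nonsyn_classes = np.array(list(_NONSYN_CLASS_PROBS))
    nonsyn_p = np.array(list(_NONSYN_CLASS_PROBS.values()))
    silent_classes = np.array(list(_SILENT_CLASS_PROBS))
    silent_p = np.array(list(_SILENT_CLASS_PROBS.values()))
    rates = np.where(is_mut, config.background_mutation_rate_mut,
                     config.background_mutation_rate_wt)
    n_bg = rng_mut.poisson(rates)
    n_silent = rng_mut.poisson(rates * _SILENT_PER_NONSYN)
    n_query = np.where(is_mut, 1 + rng_mut.poisson(0.3, size=n), 0)
    ids_arr = np.array(sample_ids)
    counts = n_bg + n_silent + n_query
    sample_col = np.repeat(ids_arr, counts)
    # per-sample layout: background nonsyn rows, then silent-ish rows,
    # then query-gene rows
    gene_col = np.empty(counts.sum(), dtype=object)
    class_col = np.empty(counts.sum(), dtype=object)
    bg_mask = np.zeros(counts.sum(), dtype=bool)
    silent_mask = np.zeros(counts.sum(), dtype=bool)
    pos = 0
    for i in range(n):
        bg_mask[pos:pos + n_bg[i]] = True
        silent_mask[pos + n_bg[i]:pos + n_bg[i] + n_silent[i]] = True
        pos += counts[i]
    query_mask = ~(bg_mask | silent_mask)
    gene_col[bg_mask | silent_mask] = rng_mut.choice(
        bg_pool, size=int(bg_mask.sum() + silent_mask.sum()))
    gene_col[query_mask] = query_gene
    class_col[bg_mask] = rng_mut.choice(nonsyn_classes, size=int(bg_mask.sum()), p=nonsyn_p)
    class_col[silent_mask] = rng_mut.choice(silent_classes, size=int(silent_mask.sum()),
                                            p=silent_p)
    class_col[query_mask] = rng_mut.choice(nonsyn_classes, size=int(query_mask.sum()),
                                           p=nonsyn_p)
    mutations = pd.DataFrame(
        {
            "sample_id": sample_col,
            "gene": gene_col,
            "variant_classification": class_col,
            "assay_id": config.assay,
        }
    )

    # --- expression -----------------------------------------------------
    rng_expr = _rng(config.seed, _SS_EXPRESSION)
    genes, immune_genes = _gene_universe(config.n_genes)
    base = np.clip(rng_expr.normal(5.0, 2.0, size=len(genes)), 0.1, None)
    mat = base[:, None] + rng_expr.normal(0.0, 1.0, size=(len(genes), n))
    immune_mask = np.isin(genes, immune_genes)
    mat[np.ix_(immune_mask, is_mut)] += config.immune_effect
    mat = np.clip(mat, 0.0, None)
    expression = ExpressionMatrix(
        pd.DataFrame(np.round(mat, 4), index=pd.Index(genes, name="gene"), columns=sample_ids),
        scale="log2p1",
    )

    # --- cell fractions and leukocyte fraction --------------------------
    rng_frac = _rng(config.seed, _SS_FRACTIONS)
    lymphoid = np.isin(CIBERSORT_CATEGORIES, LYMPHOCYTE_CATEGORIES)
    alphas = np.where(lymphoid, 1.0, 1.5)
    boost = math.exp(0.4 * config.immune_effect)
    # Dirichlet via normalized gamma draws, vectorized over samples
    alpha_mat = np.tile(alphas, (n, 1))
    alpha_mat[np.ix_(is_mut, lymphoid)] *= boost
    gammas = rng_frac.gamma(alpha_mat)
    fracs = gammas / gammas.sum(axis=1, keepdims=True)
    cell_fractions = pd.DataFrame(
        fracs, index=pd.Index(sample_ids, name="sample_id"), columns=CIBERSORT_CATEGORIES
    )
    leuk_a = 2.0 + (config.immune_effect * is_mut)
    leukocyte = pd.Series(
        rng_frac.beta(leuk_a, 4.0 * np.ones(n)),
        index=pd.Index(sample_ids, name="sample_id"),
        name="leukocyte_fraction",
    )

    return SyntheticCohort(
        mutations=mutations,
        manifest=list(sample_ids),
        clinical=clinical,
        expression=expression,
        cell_fractions=cell_fractions,
        leukocyte_fractions=leukocyte,
        truth={"config": asdict(config), "query_gene": query_gene, "arm": arm},
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Serialize a cohort: MAF-dialect TSV, clinical TSV, expression TSV,
    one-sample-per-line manifest, cell fractions TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    maf = cohort.mutations.rename(
        columns={
            "sample_id": "Tumor_Sample_Barcode",
            "gene": "Hugo_Symbol",
            "variant_classification": "Variant_Classification",
        }
    )
    paths["maf"] = outdir / "mutations.maf.tsv"
    maf.to_csv(paths["maf"], sep="\t", index=False)

    clin = pd.DataFrame([
        {
            "sample_id": r.sample_id,
            "best_response": r.best_response,
            "sd_duration_months": r.sd_duration_months,
            "pfs_months": r.pfs_months,
            "pfs_event": r.pfs_event,
            "os_months": r.os_months,
            "os_event": r.os_event,
            "cancer_type": r.cancer_type,
            "drug_class": r.drug_class,
            "pdl1_status": r.pdl1_status,
        }
        for r in cohort.clinical
    ])
    paths["clinical"] = outdir / "clinical.tsv"
    clin.to_csv(paths["clinical"], sep="\t", index=False)

    paths["expression"] = outdir / "expression.tsv"
    cohort.expression.write_tsv(paths["expression"])

    paths["manifest"] = outdir / "manifest.txt"
    paths["manifest"].write_text("\n".join(cohort.manifest) + "\n")

    fractions = cohort.cell_fractions.copy()
    fractions["leukocyte_fraction"] = cohort.leukocyte_fractions
    paths["cell_fractions"] = outdir / "cell_fractions.tsv"
    fractions.to_csv(paths["cell_fractions"], sep="\t")

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2, sort_keys=True))
    return paths
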