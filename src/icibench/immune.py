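"""Expression-derived immune scores for arm-wise contrasts.

Implements the scoring battery used to compare the immune landscape of
mutant vs wildtype tumors:

* **ssGSEA** — single-sample gene-set enrichment: per sample, genes are
  ranked by expression and the score is the running difference between
  the rank-weighted in-set ECDF (weight ``rank**alpha``, alpha = 0.25)
  and the uniform out-of-set ECDF, summed over the ranked list.  Scores
  depend on ranks only, so they are invariant to any strictly increasing
  transform of a sample's expression.
* **MCP-style population scores** — arithmetic mean of log2(x+1) marker
  expression per cell population.
* **CYT** — cytolytic activity, the geometric mean of GZMA and PRF1 on
  the linear scale with a 0.01 pseudocount.
* **NOTCH-pathway score** — mean log2(x+1) expression of the activated
  genes minus that of the repressed genes.
* **Lymphocyte / TIL fraction** — the lymphoid share of the CIBERSORT
  immune compartment, and its product with the methylation-derived
  leukocyte fraction.

Expression matrices carry an explicit scale tag (``linear`` or
``log2p1``); conversions are driven by the tag, never guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .stats import TestResult, wilcoxon_rank_sum

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "SignatureScores",
    "read_gmt",
    "write_gmt",
    "ssgsea",
    "mcp_scores",
    "cyt_score",
    "pathway_score",
    "lymphocyte_fraction",
    "til_fraction",
    "compare_by_arm",
    "CIBERSORT_CATEGORIES",
    "LYMPHOCYTE_CATEGORIES",
]

#: the 22 CIBERSORT immune-cell categories (relative-fraction convention)
CIBERSORT_CATEGORIES = (
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
)

#: lymphoid categories aggregated into the lymphocyte fraction
LYMPHOCYTE_CATEGORIES = (
    "Plasma cells",
    "NK cells activated",
    "NK cells resting",
    "T cells CD8",
    "T cells gamma delta",
    "T cells regulatory (Tregs)",
    "T cells follicular helper",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "B cells naive",
    "B cells memory",
)

CYT_GENES = ("GZMA", "PRF1")
CYT_PSEUDOCOUNT = 0.01
SSGSEA_ALPHA = 0.25


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with an explicit scale tag."""

    values: pd.DataFrame  # index = gene symbols (upper case), columns = samples
    scale: str = "linear"  # 'linear' or 'log2p1'

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2p1"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        self.values = self.values.copy()
        self.values.index = self.values.index.astype(str).str.upper()
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative values on linear scale")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def to_log2p1(self) -> "ExpressionMatrix":
        if self.scale == "log2p1":
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), scale="log2p1")

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.exp2(self.values) - 1.0, scale="linear")

    @classmethod
    def read_tsv(cls, path, scale: str = "linear") -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), scale=scale)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional direction tag per set."""

    sets: dict[str, tuple[str, ...]]
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            genes = tuple(dict.fromkeys(g.upper() for g in genes))
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = genes
        self.sets = clean
        for name, tag in self.directions.items():
            if tag not in ("activated", "repressed", "none"):
                raise ValueError(f"unknown direction tag {tag!r} for set {name!r}")

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> genes...).

    A description field of ``activated``/``repressed`` is picked up as
    the set's direction tag.
    """
    sets, directions = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {line!r}")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = tuple(genes)
            if desc in ("activated", "repressed"):
                directions[name] = desc
    return GeneSetCollection(sets, directions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.directions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


@dataclass
class SignatureScores:
    """Per-(set, sample) scores plus coverage and per-set error entries."""

    scores: pd.DataFrame  # index = set names, columns = samples
    method: str
    coverage: dict[str, float] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def _sample_ssgsea(expr_col: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    # ranks: highest expression gets the largest rank; ties share the
    # average rank so the weights are permutation-stable within a tie
    n = expr_col.size
    ranks = rankdata(expr_col, method="average")
    order = np.argsort(-expr_col, kind="stable")  # descending walk
    in_ordered = in_set[order]
    w = ranks[order] ** alpha
    w_in = np.where(in_ordered, w, 0.0)
    cdf_in = np.cumsum(w_in) / w_in.sum()
    n_out = n - in_ordered.sum()
    cdf_out = np.cumsum(~in_ordered) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea(expr: ExpressionMatrix, sets: GeneSetCollection,
           alpha: float = SSGSEA_ALPHA, normalize: bool = False) -> SignatureScores:
    """Single-sample GSEA enrichment scores for each (set, sample) pair.

    Genes absent from the matrix are dropped from the set, with the
    retained fraction recorded in ``coverage``.  A set with no overlap
    (or covering the whole gene universe, which has no complement) gets
    an entry in ``errors`` and NaN scores; other sets are still scored.
    When ``normalize`` is on, all scores are divided by the overall range
    (max - min) across samples and sets.
    """
    genes = expr.genes
    if len(genes) < 2:
        raise ValueError("need at least two genes for ranking")
    mat = expr.values.to_numpy(dtype=float)
    out = pd.DataFrame(np.nan, index=list(sets), columns=expr.samples, dtype=float)
    coverage, errors = {}, {}
    for name in sets:
        members = set(sets[name])
        mask = np.asarray(genes.isin(members))
        coverage[name] = mask.sum() / len(members)
        if mask.sum() == 0:
            errors[name] = "no overlap with expression matrix"
            continue
        if mask.all():
            errors[name] = "set covers the entire gene universe (empty complement)"
            continue
        out.loc[name] = [
            _sample_ssgsea(mat[:, j], mask, alpha) for j in range(mat.shape[1])
        ]
    if normalize:
        rng_ = np.nanmax(out.to_numpy()) - np.nanmin(out.to_numpy())
        if rng_ > 0:
            out = out / rng_
    return SignatureScores(scores=out, method="ssgsea", coverage=coverage, errors=errors)


def mcp_scores(expr: ExpressionMatrix, marker_sets: GeneSetCollection) -> SignatureScores:
    """MCP-style abundance: mean log2(x+1) of each population's markers."""
    log_expr = expr.to_log2p1()
    out = pd.DataFrame(np.nan, index=list(marker_sets), columns=expr.samples, dtype=float)
    coverage, errors = {}, {}
    for name in marker_sets:
        members = [g for g in marker_sets[name] if g in log_expr.genes]
        coverage[name] = len(members) / len(marker_sets[name])
        if not members:
            errors[name] = "no marker genes present in expression matrix"
            continue
        out.loc[name] = log_expr.values.loc[members].mean(axis=0)
    return SignatureScores(scores=out, method="mcp", coverage=coverage, errors=errors)


def cyt_score(expr: ExpressionMatrix) -> pd.Series:
    """Cytolytic activity: geometric mean of GZMA and PRF1 (linear scale).

    A pseudocount of 0.01 keeps the score finite when either gene is
    silent: sqrt((GZMA + 0.01) * (PRF1 + 0.01)).
    """
    linear = expr.to_linear()
    missing = [g for g in CYT_GENES if g not in linear.genes]
    if missing:
        raise ValueError(f"cytolytic-activity gene(s) absent: {missing}")
    gzma = linear.values.loc["GZMA"].astype(float)
    prf1 = linear.values.loc["PRF1"].astype(float)
    return np.sqrt((gzma + CYT_PSEUDOCOUNT) * (prf1 + CYT_PSEUDOCOUNT)).rename("cyt")


def pathway_score(expr: ExpressionMatrix, activated, repressed) -> pd.Series:
    """Mean log2(x+1) of activated genes minus that of repressed genes."""
    log_expr = expr.to_log2p1()
    act = [g.upper() for g in activated if g.upper() in log_expr.genes]
    rep = [g.upper() for g in repressed if g.upper() in log_expr.genes]
    if not act or not rep:
        raise ValueError(
            "pathway score needs both directions present; "
            f"activated overlap {len(act)}/{len(list(activated))}, "
            f"repressed overlap {len(rep)}/{len(list(repressed))}"
        )
    score = log_expr.values.loc[act].mean(axis=0) - log_expr.values.loc[rep].mean(axis=0)
    score.attrs["coverage"] = {
        "activated": len(act) / len(list(activated)),
        "repressed": len(rep) / len(list(repressed)),
    }
    return score.rename("pathway_score")


def lymphocyte_fraction(fractions: pd.DataFrame) -> pd.Series:
    """Lymphoid share of the immune compartment per sample.

    ``fractions`` is samples x the 22 CIBERSORT categories (relative
    fractions summing to 1).  The lymphocyte fraction sums exactly the
    categories in :data:`LYMPHOCYTE_CATEGORIES`.
    """
    missing = [c for c in CIBERSORT_CATEGORIES if c not in fractions.columns]
    if missing:
        raise ValueError(f"missing cell-fraction column(s): {missing}")
    totals = fractions[list(CIBERSORT_CATEGORIES)].sum(axis=1)
    if not np.allclose(totals, 1.0, atol=1e-6):
        bad = totals[(totals - 1.0).abs() > 1e-6].index.tolist()
        raise ValueError(f"cell fractions do not sum to 1 for sample(s): {bad}")
    return fractions[list(LYMPHOCYTE_CATEGORIES)].sum(axis=1).rename("lymphocyte_fraction")


def til_fraction(leukocyte_fraction, lymph_fraction):
    """Tumor-infiltrating lymphocyte fraction = leukocyte x lymphocyte.

    Both inputs live in [0, 1]; the product is bounded by each factor.
    Accepts scalars or aligned pandas Series.
    """
    leuk = pd.Series(leukocyte_fraction) if np.isscalar(leukocyte_fraction) else pd.Series(leukocyte_fraction)
    lymph = pd.Series(lymph_fraction) if np.isscalar(lymph_fraction) else pd.Series(lymph_fraction)
    for name, s in (("leukocyte_fraction", leuk), ("lymphocyte_fraction", lymph)):
        if ((s < 0) | (s > 1)).any():
            raise ValueError(f"{name} outside [0, 1]")
    out = (leuk * lymph).rename("til_fraction")
    return float(out.iloc[0]) if np.isscalar(leukocyte_fraction) and np.isscalar(lymph_fraction) else out


def compare_by_arm(scores: pd.DataFrame, status: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mutant-vs-wildtype Wilcoxon comparison.

    ``scores`` is features x samples; ``status`` a per-sample MUT/WT
    table.  Returns one row per feature with the two-sided p, per-arm
    medians, enrichment direction and -log10 p (volcano-ready), sorted
    by ascending p.  Features constant across all samples are flagged
    degenerate (p = 1).
    """
    common = [s for s in scores.columns if s in status.index]
    arm = status.loc[common, "status"]
    mut_samples = [s for s in common if arm[s] == "MUT"]
    wt_samples = [s for s in common if arm[s] == "WT"]
    if len(mut_samples) < 2 or len(wt_samples) < 2:
        raise ValueError(
            f"need >= 2 overlapping samples per arm, got {len(mut_samples)} MUT / {len(wt_samples)} WT"
        )
    rows = []
    for feature, values in scores.iterrows():
        x = values[mut_samples].to_numpy(dtype=float)
        y = values[wt_samples].to_numpy(dtype=float)
        if np.isnan(x).all() or np.isnan(y).all():
            continue
        res: TestResult = wilcoxon_rank_sum(x[~np.isnan(x)], y[~np.isnan(y)])
        med_mut, med_wt = float(np.nanmedian(x)), float(np.nanmedian(y))
        direction = "MUT" if med_mut > med_wt else ("WT" if med_wt > med_mut else "none")
        rows.append(
            {
                "feature": feature,
                "p": res.p_value,
                "median_mut": med_mut,
                "median_wt": med_wt,
                "direction": direction,
                "neglog10_p": -math.log10(res.p_value) if res.p_value > 0 else math.inf,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("feature").sort_values("p", kind="stable")
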