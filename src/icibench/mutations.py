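"""MAF ingestion, nonsynonymous filtering, gene-status calls and TMB.

The mutation side of the pipeline works on a tidy variant table (one row
per somatic call) with the MAF-dialect columns ``Tumor_Sample_Barcode``,
``Hugo_Symbol`` and ``Variant_Classification``, plus an assay identifier
that maps each sample to a sequencing footprint for TMB normalization.

A sample is called mutant for a query gene when it carries at least one
*nonsynonymous* variant of that gene; manifest samples with no qualifying
variant are wildtype.  Tumor mutational burden is the nonsynonymous count
divided by the assay's exonic coverage in megabases (38 Mb for whole-exome
data; 1.22/1.06/0.98 Mb for the 468/410/341-gene targeted panels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2

logger = logging.getLogger(__name__)

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "RECOGNIZED_CLASSES",
    "PANEL_COVERAGE_MB",
    "PanelSpec",
    "read_maf",
    "filter_nonsynonymous",
    "call_gene_status",
    "call_geneset_status",
    "compute_tmb",
    "cooccurrence_table",
    "NOTCH_FAMILY",
    "HOMOLOGOUS_REPAIR_GENES",
]

#: the six nonsynonymous classes counted for mutation status and TMB
#: (frameshift expands to deletion and insertion tokens; in-frame indels
#: are deliberately excluded)
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: full controlled vocabulary accepted on input; anything else is rejected
RECOGNIZED_CLASSES = NONSYNONYMOUS_CLASSES | frozenset(
    {
        "Silent",
        "In_Frame_Del",
        "In_Frame_Ins",
        "3'UTR",
        "5'UTR",
        "Intron",
        "RNA",
        "IGR",
        "5'Flank",
        "3'Flank",
        "Splice_Region",
        "Targeted_Region",
    }
)

#: exonic coverage (Mb) per assay, used as the TMB denominator
PANEL_COVERAGE_MB = {
    "WES": 38.0,
    "IMPACT468": 1.22,
    "IMPACT410": 1.06,
    "IMPACT341": 0.98,
}

NOTCH_FAMILY = ("NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4")
HOMOLOGOUS_REPAIR_GENES = ("ATR", "ATM", "BRCA1", "BRCA2", "MUTYH")

_MAF_COLUMNS = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_classification",
}


@dataclass(frozen=True)
class PanelSpec:
    """Sequencing assay footprint used to normalize mutation counts."""

    assay_id: str
    exonic_coverage_mb: float

    def __post_init__(self) -> None:
        if self.exonic_coverage_mb <= 0:
            raise ValueError("exonic coverage must be positive")

    @classmethod
    def default(cls, assay_id: str) -> "PanelSpec":
        try:
            return cls(assay_id, PANEL_COVERAGE_MB[assay_id])
        except KeyError:
            raise ValueError(
                f"unknown assay_id {assay_id!r}; known: {sorted(PANEL_COVERAGE_MB)}"
            ) from None


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    unknown = set(records["variant_classification"]) - RECOGNIZED_CLASSES
    if unknown:
        raise ValueError(
            f"unrecognized Variant_Classification token(s): {sorted(unknown)}"
        )
    out = records.copy()
    out["gene"] = out["gene"].str.upper()
    return out


def read_maf(path, manifest) -> pd.DataFrame:
    """Read a MAF-dialect TSV into a validated variant table.

    Column order is irrelevant; extra columns are ignored.  Every row's
    sample must appear in ``manifest`` (unsequenced patients can never be
    silently treated as wildtype).  When no assay column is present, all
    samples default to WES with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file missing mandatory column(s): {missing}")
    out = df.rename(columns=_MAF_COLUMNS)
    if "assay_id" not in out.columns:
        logger.warning("no assay_id column in %s; defaulting every sample to WES", path)
        out["assay_id"] = "WES"
    out = out[["sample_id", "gene", "variant_classification", "assay_id"]]
    out = _validate_records(out)
    manifest = set(manifest)
    strays = sorted(set(out["sample_id"]) - manifest)
    if strays:
        raise ValueError(f"sample(s) in MAF but absent from manifest: {strays}")
    return out.reset_index(drop=True)


def filter_nonsynonymous(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only the six nonsynonymous variant classes, preserving order."""
    records = _validate_records(records)
    keep = records["variant_classification"].isin(NONSYNONYMOUS_CLASSES)
    return records[keep].reset_index(drop=True)


def _status_frame(manifest, counts: pd.Series, mut_label: str, wt_label: str) -> pd.DataFrame:
    manifest = list(dict.fromkeys(manifest))
    if not manifest:
        raise ValueError("manifest is empty")
    n = counts.reindex(manifest).fillna(0).astype(int)
    status = np.where(n.values > 0, mut_label, wt_label)
    return pd.DataFrame({"status": status, "n_variants": n.values}, index=pd.Index(manifest, name="sample_id"))


def call_gene_status(records: pd.DataFrame, manifest, gene: str) -> pd.DataFrame:
    """Per-sample MUT/WT status for one gene from nonsynonymous records.

    A sample is MUT iff it carries >= 1 qualifying variant of ``gene``
    (multiplicity ignored); all other manifest samples are WT.
    """
    gene = gene.upper()
    hits = records[records["gene"].str.upper() == gene]
    counts = hits.groupby("sample_id").size()
    return _status_frame(manifest, counts, "MUT", "WT")


def call_geneset_status(records: pd.DataFrame, manifest, genes) -> pd.DataFrame:
    """Altered/unaltered status by the union rule over a gene set."""
    genes = {g.upper() for g in genes}
    if not genes:
        raise ValueError("gene set is empty")
    hits = records[records["gene"].str.upper().isin(genes)]
    counts = hits.groupby("sample_id").size()
    return _status_frame(manifest, counts, "MUT", "WT")


def compute_tmb(records: pd.DataFrame, manifest, panels=None, assay_map=None) -> pd.Series:
    """Tumor mutational burden (nonsynonymous mutations / Mb) per sample.

    ``records`` must already be nonsynonymous-filtered.  The denominator
    comes from each sample's assay: either the per-record ``assay_id``
    column (which must be consistent within a sample) or an explicit
    ``assay_map`` of sample -> assay.  Manifest samples without records
    get TMB 0.
    """
    panels = panels or {a: PanelSpec.default(a) for a in PANEL_COVERAGE_MB}
    manifest = list(dict.fromkeys(manifest))
    if not manifest:
        raise ValueError("manifest is empty")
    counts = records.groupby("sample_id").size()
    if assay_map is None:
        per_sample = records.groupby("sample_id")["assay_id"].agg(lambda s: sorted(set(s)))
        mixed = per_sample[per_sample.str.len() > 1]
        if not mixed.empty:
            raise ValueError(f"mixed assay_ids within sample(s): {mixed.to_dict()}")
        assay_map = {s: a[0] for s, a in per_sample.items()}
    tmb = {}
    for sample in manifest:
        n = int(counts.get(sample, 0))
        if n == 0:
            tmb[sample] = 0.0
            continue
        assay = assay_map.get(sample, "WES")
        if assay not in panels:
            raise ValueError(f"unknown assay_id {assay!r} for sample {sample!r}")
        tmb[sample] = n / panels[assay].exonic_coverage_mb
    return pd.Series(tmb, name="tmb").reindex(manifest)


def cooccurrence_table(status_a: pd.DataFrame, status_b: pd.DataFrame) -> ContingencyTable2x2:
    """2x2 co-occurrence counts of two per-sample status tables.

    Rows: A mutant / A wildtype; columns: B altered / B unaltered.
    """
    ua, ub = set(status_a.index), set(status_b.index)
    if ua != ub:
        raise ValueError(
            f"sample universes differ; symmetric difference: {sorted(ua ^ ub)}"
        )
    b = status_b.loc[status_a.index, "status"]
    a_mut = status_a["status"].values == "MUT"
    b_mut = b.values == "MUT"
    return ContingencyTable2x2(
        a=int(np.sum(a_mut & b_mut)),
        b=int(np.sum(a_mut & ~b_mut)),
        c=int(np.sum(~a_mut & b_mut)),
        d=int(np.sum(~a_mut & ~b_mut)),
    )
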