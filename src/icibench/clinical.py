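"""Clinical endpoint definitions: objective response and durable benefit.

Best response follows RECIST 1.1 categories (CR/PR/SD/PD).  A patient is
a *responder* when the best response is CR or PR; the objective response
rate (ORR) is the responder fraction.  Durable clinical benefit (DCB) is
CR/PR, or SD lasting strictly more than 6 months; SD of exactly 6 months
and all PD are no durable benefit (NDB).  Supplied PFS/OS times are
assumed origin-adjusted (ICI start for treated cohorts) and are consumed
as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .stats import ContingencyTable2x2

__all__ = [
    "RESPONSE_CATEGORIES",
    "DCB_SD_THRESHOLD_MONTHS",
    "ClinicalRecord",
    "classify_response",
    "classify_dcb",
    "build_benefit_table",
    "read_clinical_table",
]

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")
DCB_SD_THRESHOLD_MONTHS = 6.0


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient outcomes for one immunotherapy course."""

    sample_id: str
    best_response: str
    pfs_months: float
    pfs_event: int
    os_months: float
    os_event: int
    cancer_type: str
    drug_class: str = "monotherapy"
    sd_duration_months: Optional[float] = None
    pdl1_status: Optional[str] = None

    def __post_init__(self) -> None:
        if self.best_response not in RESPONSE_CATEGORIES:
            raise ValueError(f"unknown best_response {self.best_response!r}")
        if self.pfs_months < 0 or self.os_months < 0:
            raise ValueError("survival times must be nonnegative")
        if self.pfs_event not in (0, 1) or self.os_event not in (0, 1):
            raise ValueError("event flags must be 0 or 1")
        if self.best_response == "SD":
            if self.sd_duration_months is None:
                raise ValueError(f"SD record {self.sample_id!r} lacks sd_duration_months")
            if self.sd_duration_months < 0:
                raise ValueError("sd_duration_months must be nonnegative")
        elif self.sd_duration_months is not None:
            raise ValueError("sd_duration_months only meaningful for SD records")
        if self.drug_class not in ("monotherapy", "combination"):
            raise ValueError(f"unknown drug_class {self.drug_class!r}")
        if self.pdl1_status not in (None, "positive", "negative", "missing"):
            raise ValueError(f"unknown pdl1_status {self.pdl1_status!r}")


def classify_response(record: ClinicalRecord) -> bool:
    """True iff the best response is an objective response (CR or PR)."""
    return record.best_response in ("CR", "PR")


def classify_dcb(record: ClinicalRecord) -> str:
    """'DCB' for CR/PR or SD lasting > 6 months, 'NDB' otherwise."""
    if classify_response(record):
        return "DCB"
    if record.best_response == "SD":
        if record.sd_duration_months is None:  # defense: frozen dataclass enforces it
            raise ValueError(f"SD record {record.sample_id!r} lacks sd_duration_months")
        return "DCB" if record.sd_duration_months > DCB_SD_THRESHOLD_MONTHS else "NDB"
    return "NDB"


def build_benefit_table(clinical, status: pd.DataFrame, endpoint: str):
    """Contingency table of biomarker arm x favorable outcome.

    ``endpoint`` is ``"ORR"`` (favorable = responder) or ``"DCB"``
    (favorable = durable benefit).  Returns the 2x2 table plus the
    per-arm favorable rates as percentages rounded to one decimal:
    ``(table, rate_mut_pct, rate_wt_pct)``.
    """
    if endpoint not in ("ORR", "DCB"):
        raise ValueError(f"endpoint must be 'ORR' or 'DCB', got {endpoint!r}")
    by_id = {r.sample_id: r for r in clinical}
    if set(by_id) != set(status.index):
        raise ValueError(
            "clinical and status sample universes differ; symmetric difference: "
            f"{sorted(set(by_id) ^ set(status.index))}"
        )
    a = b = c = d = 0
    for sample_id, row in status.iterrows():
        rec = by_id[sample_id]
        favorable = classify_response(rec) if endpoint == "ORR" else classify_dcb(rec) == "DCB"
        if row["status"] == "MUT":
            a, b = (a + 1, b) if favorable else (a, b + 1)
        else:
            c, d = (c + 1, d) if favorable else (c, d + 1)
    table = ContingencyTable2x2(a, b, c, d)
    rate_mut, rate_wt = table.row_rates()
    return table, rate_mut, rate_wt


def read_clinical_table(path) -> list[ClinicalRecord]:
    """Load a clinical TSV whose columns mirror ClinicalRecord fields."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        sd = getattr(row, "sd_duration_months", None)
        if sd is not None and pd.isna(sd):
            sd = None
        pdl1 = getattr(row, "pdl1_status", None)
        if pdl1 is not None and pd.isna(pdl1):
            pdl1 = None
        records.append(
            ClinicalRecord(
                sample_id=str(row.sample_id),
                best_response=str(row.best_response),
                pfs_months=float(row.pfs_months),
                pfs_event=int(row.pfs_event),
                os_months=float(row.os_months),
                os_event=int(row.os_event),
                cancer_type=str(row.cancer_type),
                drug_class=str(row.drug_class),
                sd_duration_months=None if sd is None else float(sd),
                pdl1_status=None if pdl1 is None else str(pdl1),
            )
        )
    return records


def clinical_to_frame(clinical) -> pd.DataFrame:
    """Tidy DataFrame view of a list of ClinicalRecord (for survival fits)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in clinical],
            "best_response": [r.best_response for r in clinical],
            "sd_duration_months": [r.sd_duration_months for r in clinical],
            "pfs_months": [r.pfs_months for r in clinical],
            "pfs_event": [r.pfs_event for r in clinical],
            "os_months": [r.os_months for r in clinical],
            "os_event": [r.os_event for r in clinical],
            "cancer_type": [r.cancer_type for r in clinical],
            "drug_class": [r.drug_class for r in clinical],
            "pdl1_status": [r.pdl1_status for r in clinical],
        }
    ).set_index("sample_id")
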