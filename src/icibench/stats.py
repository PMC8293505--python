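"""Categorical and rank-based association tests.

Two statistics drive the biomarker/response association analysis: a
two-sided Fisher's exact test on 2x2 responder/benefit tables (with the
minimum-likelihood two-sided convention used by mainstream statistical
environments) and the Wilcoxon rank-sum comparison for continuous scores
between the mutant and wildtype arms.  Both delegate the numerics to
scipy but wrap them in explicit degenerate-case handling so that a
pipeline run never turns a structural zero into an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact",
    "wilcoxon_rank_sum",
]

#: group size above which the rank-sum test switches from exact
#: enumeration to the tie-corrected normal approximation
EXACT_RANKSUM_MAX_N = 25


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows index the biomarker arm, columns the outcome.

    Layout::

        [[a, b],      a = MUT & favorable, b = MUT & unfavorable
         [c, d]]      c = WT  & favorable, d = WT  & unfavorable
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any((not isinstance(x, (int, np.integer))) or x < 0 for x in cells):
            raise ValueError(f"cell counts must be nonnegative integers, got {cells}")
        if sum(cells) < 1:
            raise ValueError("contingency table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        """Sample (unconditional) odds ratio a*d / b*c; inf when b*c == 0 < a*d."""
        num = self.a * self.d
        den = self.b * self.c
        if den == 0:
            return math.inf if num > 0 else math.nan
        return num / den

    def row_rates(self) -> tuple[float, float]:
        """Per-arm favorable rate as a percentage rounded to one decimal."""
        r1 = 100.0 * self.a / (self.a + self.b) if (self.a + self.b) else 0.0
        r2 = 100.0 * self.c / (self.c + self.d) if (self.c + self.d) else 0.0
        return round(r1, 1), round(r2, 1)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p_value: float
    method: str
    sidedness: str = "two-sided"
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose likelihood does not exceed that of the
    observed table (minimum-likelihood convention).  A table with a zero
    margin carries no information about association: it is reported as
    p = 1 with ``degenerate=True`` rather than raising.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return TestResult(
            statistic=table.odds_ratio,
            p_value=1.0,
            method="fisher-exact",
            degenerate=True,
            extra={"reason": "zero margin"},
        )
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(statistic=table.odds_ratio, p_value=float(min(p, 1.0)), method="fisher-exact")


def _rank_sum_W(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum())


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration of the rank-sum distribution when both groups
    have at most ``EXACT_RANKSUM_MAX_N`` observations and the pooled data
    are tie-free; otherwise the normal approximation with tie-corrected
    variance and a 0.5 continuity correction.  Statistic reported is the
    rank-sum W of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    W = _rank_sum_W(x, y)
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=W,
            p_value=1.0,
            method="wilcoxon-rank-sum",
            degenerate=True,
            extra={"reason": "all values identical"},
        )
    has_ties = np.unique(pooled).size < pooled.size
    small = min(x.size, y.size) <= EXACT_RANKSUM_MAX_N
    if small and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        statistic=W,
        p_value=float(res.pvalue),
        method="wilcoxon-rank-sum",
        extra={"approximation": method, "U": float(res.statistic)},
    )
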