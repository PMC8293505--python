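"""Survival analysis: Kaplan-Meier, log-rank, Cox PH, C-index, resampling.

All estimators are right-censored time-to-event machinery on (time,
event) pairs in months.  Model fitting is delegated to lifelines
(Kaplan-Meier product-limit, Mantel-Cox log-rank, Efron-tie-corrected
Cox partial likelihood); Harrell's concordance is computed here because
the pipeline's pair-usability convention (a strictly smaller time that
is an event) differs from lifelines' handling of tied times.  The module
fixes the conventions the pipeline relies on:

* KM median survival is the smallest observed time with S(t) <= 0.5 and
  is ``None`` ("not reached") while the curve stays above 0.5;
* the Cox hazard ratio indexes the mutant arm (WT = 0, MUT = 1), so
  HR < 1 means longer survival for mutant patients;
* the C-index is oriented so that *higher risk scores must predict
  shorter survival*; the caller chooses the sign for raw binary markers;
* the stability procedure repeatedly downsamples the wildtype arm to the
  mutant arm's size and re-estimates the WT median and the Cox HR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .stats import TestResult

__all__ = [
    "KMCurve",
    "CoxResult",
    "ResamplingSummary",
    "km_fit",
    "logrank_test",
    "cox_fit",
    "build_design",
    "c_index",
    "resample_stability",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate over the distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    median: Optional[float]  # None = not reached

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxResult:
    """Cox proportional-hazards fit: one row per covariate."""

    summary: pd.DataFrame  # columns: coef, se, hr, ci_lower, ci_upper, p
    log_likelihood: float

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


@dataclass(frozen=True)
class ResamplingSummary:
    """Aggregate of the wildtype-downsampling stability procedure."""

    n_iterations: int
    seed: int
    wt_median_pfs: np.ndarray  # per-iteration WT-subsample KM median (NaN = not reached)
    hr: np.ndarray  # per-iteration Cox HR MUT vs WT subsample (NaN = failed/degenerate)
    mean_wt_median: float
    ci_wt_median: tuple[float, float]  # empirical 2.5-97.5 percentiles
    mean_hr: float
    ci_hr: tuple[float, float]
    n_missing_median: int
    n_missing_hr: int
    extra: dict = field(default_factory=dict)


def _check_times(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("need at least one record")
    if (time < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event flags must be 0/1")
    return time, event.astype(int)


def km_fit(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censorings tied with an event time remain at risk for that event
    (the standard events-before-censorings convention).
    """
    time, event = _check_times(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy(dtype=float)
    median = None
    below = np.nonzero(surv <= 0.5)[0]
    if below.size:
        median = float(times[below[0]])
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        median=median,
    )


def logrank_test(time_a, event_a, time_b, event_b) -> TestResult:
    """Two-group Mantel-Cox log-rank test (chi-square, 1 df)."""
    time_a, event_a = _check_times(time_a, event_a)
    time_b, event_b = _check_times(time_b, event_b)
    if event_a.sum() + event_b.sum() == 0:
        return TestResult(
            statistic=0.0,
            p_value=1.0,
            method="logrank",
            degenerate=True,
            extra={"reason": "no events in either group"},
        )
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return TestResult(statistic=float(res.test_statistic), p_value=float(res.p_value), method="logrank")


def build_design(df: pd.DataFrame, binary: str, categorical=()) -> pd.DataFrame:
    """Numeric design matrix: binary status column plus one-hot categories.

    The reference level of each categorical covariate is its
    alphabetically first category, dropped deterministically.
    """
    cols = {binary: df[binary].astype(float)}
    for cat in categorical:
        levels = sorted(df[cat].astype(str).unique())
        for level in levels[1:]:
            cols[f"{cat}={level}"] = (df[cat].astype(str) == level).astype(float)
    return pd.DataFrame(cols, index=df.index)


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str, covariates=None) -> CoxResult:
    """Cox proportional-hazards fit with Efron tie handling.

    ``df`` holds the duration/event columns plus numeric covariates
    (see :func:`build_design` for one-hot encoding).  Wald 95% CIs are
    exp(coef +/- 1.96 se).  A covariate with no variation gets
    coefficient 0 / HR 1 rather than being dropped.
    """
    covariates = list(covariates) if covariates is not None else [
        c for c in df.columns if c not in (duration_col, event_col)
    ]
    data = df[[duration_col, event_col, *covariates]].astype(float)
    if data[event_col].sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    constant = [c for c in covariates if data[c].nunique() <= 1]
    varying = [c for c in covariates if c not in constant]
    if varying:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cph.fit(data[[duration_col, event_col, *varying]],
                        duration_col=duration_col, event_col=event_col,
                        fit_options={"precision": 1e-9, "max_steps": 500})
            except ConvergenceError as err:
                raise RuntimeError(
                    f"Cox partial-likelihood maximization failed to converge: {err}"
                ) from err
        runaway = cph.params_[cph.params_.abs() > 10].index.tolist()
        if runaway:
            raise RuntimeError(
                "monotone partial likelihood (complete separation) for "
                f"covariate(s): {runaway}"
            )
        coefs = cph.params_
        ses = cph.standard_errors_
        pvals = cph.summary["p"]
        ll = float(cph.log_likelihood_)
    else:
        coefs = pd.Series(dtype=float)
        ses = pd.Series(dtype=float)
        pvals = pd.Series(dtype=float)
        ll = float("nan")
    rows = []
    for c in covariates:
        if c in constant:
            rows.append((c, 0.0, float("nan"), 1.0, float("nan"), float("nan"), float("nan")))
        else:
            beta, se = float(coefs[c]), float(ses[c])
            rows.append((c, beta, se, float(np.exp(beta)),
                         float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)),
                         float(pvals[c])))
    summary = pd.DataFrame(
        rows, columns=["covariate", "coef", "se", "hr", "ci_lower", "ci_upper", "p"]
    ).set_index("covariate")
    return CoxResult(summary=summary, log_likelihood=ll)


def c_index(time, event, risk) -> float:
    """Harrell's concordance index of a risk score against survival.

    Usable pairs are those whose earlier time is an event; a pair is
    concordant when the higher-risk patient fails first; tied risks
    count 1/2.  Raises ``ValueError`` when no pair is usable.
    """
    time, event = _check_times(time, event)
    risk = np.asarray(risk, dtype=float)
    if risk.shape != time.shape:
        raise ValueError("risk must be defined for every record")
    # usable pair: strictly smaller time AND that earlier record is an
    # event (equal-time pairs carry no ordering information here)
    earlier = time[:, None] < time[None, :]
    usable = earlier & (event[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs: insufficient events or all times tied")
    risk_diff = risk[:, None] - risk[None, :]
    concordant = (usable & (risk_diff > 0)).sum()
    tied = (usable & (risk_diff == 0)).sum()
    return float((concordant + 0.5 * tied) / n_usable)


def resample_stability(mut: pd.DataFrame, wt: pd.DataFrame, n_iter: int = 1000,
                       seed: int = 0, duration_col: str = "time",
                       event_col: str = "event") -> ResamplingSummary:
    """Wildtype-downsampling stability of the mutant-arm hazard ratio.

    Each iteration draws ``len(mut)`` wildtype patients without
    replacement, records the WT-subsample KM median and the Cox HR of
    mutant vs subsample.  Iterations whose subsample has no event (or a
    non-convergent fit) contribute NaN and are counted as missing.
    Aggregates are the mean and the empirical 2.5-97.5 percentile
    interval of each per-iteration statistic.
    """
    n_mut = len(mut)
    if n_mut < 2 or len(wt) < n_mut:
        raise ValueError("need |wt| >= |mut| >= 2")
    rng = np.random.default_rng(seed)
    wt_times = wt[duration_col].to_numpy(dtype=float)
    wt_events = wt[event_col].to_numpy(dtype=int)
    mut_times = mut[duration_col].to_numpy(dtype=float)
    mut_events = mut[event_col].to_numpy(dtype=int)
    medians = np.full(n_iter, np.nan)
    hrs = np.full(n_iter, np.nan)
    for i in range(n_iter):
        idx = rng.choice(len(wt), size=n_mut, replace=False)
        sub_t, sub_e = wt_times[idx], wt_events[idx]
        if sub_e.sum() > 0:
            curve = km_fit(sub_t, sub_e)
            if curve.median is not None:
                medians[i] = curve.median
            if mut_events.sum() > 0:
                df = pd.DataFrame(
                    {
                        "time": np.concatenate([mut_times, sub_t]),
                        "event": np.concatenate([mut_events, sub_e]),
                        "mutant": np.concatenate([np.ones(n_mut), np.zeros(n_mut)]),
                    }
                )
                try:
                    hrs[i] = cox_fit(df, "time", "event", ["mutant"]).hr("mutant")
                except (RuntimeError, ValueError):
                    pass  # leave NaN; counted below

    def _agg(v):
        ok = v[~np.isnan(v)]
        if ok.size == 0:
            return float("nan"), (float("nan"), float("nan"))
        return float(ok.mean()), (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5)))

    mean_med, ci_med = _agg(medians)
    mean_hr, ci_hr = _agg(hrs)
    return ResamplingSummary(
        n_iterations=n_iter,
        seed=seed,
        wt_median_pfs=medians,
        hr=hrs,
        mean_wt_median=mean_med,
        ci_wt_median=ci_med,
        mean_hr=mean_hr,
        ci_hr=ci_hr,
        n_missing_median=int(np.isnan(medians).sum()),
        n_missing_hr=int(np.isnan(hrs).sum()),
    )
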