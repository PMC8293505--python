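"""Independent brute-force oracles used by the test suite.

Each function here recomputes a statistic by direct enumeration or
naive summation, written without reference to the library's fast paths
(and without lifelines/scipy's versions of the same statistic), so that
implementation and oracle stay on separate routes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Minimum-likelihood two-sided Fisher p by hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def ranksum_exact(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all rank assignments."""
    pooled = sorted(list(x) + list(y))
    n1, n = len(x), len(x) + len(y)
    ranks = list(range(1, n + 1))  # no ties assumed
    w_obs = sum(ranks[pooled.index(v)] for v in x)
    mean_w = n1 * (n + 1) / 2
    count = total = 0
    for combo in itertools.combinations(ranks, n1):
        total += 1
        if abs(sum(combo) - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def efron_log_partial_likelihood(beta: float, time, event, covariate) -> float:
    """Efron-tie-corrected Cox log partial likelihood, single covariate."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(covariate, float)
    theta = np.exp(beta * x)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        deaths = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(deaths.sum())
        sum_risk = theta[at_risk].sum()
        sum_dead = theta[deaths].sum()
        ll += beta * x[deaths].sum()
        for j in range(d):
            ll -= math.log(sum_risk - j / d * sum_dead)
    return ll


def cox_grid_maximizer(time, event, covariate, lo=-5.0, hi=5.0, tol=1e-6) -> float:
    """Brute-force maximizer of the Efron partial likelihood by
    iterative grid refinement (no derivatives)."""
    for _ in range(30):
        grid = np.linspace(lo, hi, 41)
        vals = [efron_log_partial_likelihood(b, time, event, covariate) for b in grid]
        best = int(np.argmax(vals))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        if hi - lo < tol:
            break
    return float((lo + hi) / 2)


def concordance_by_pairs(time, event, risk):
    """Harrell's C by exhaustive enumeration of usable pairs."""
    n = len(time)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if time[i] == time[j]:
                continue
            first, later = (i, j) if time[i] < time[j] else (j, i)
            if i > j:
                continue  # count unordered pairs once
            if not event[first]:
                continue  # usable only when the earlier time is an event
            den += 1
            if risk[first] > risk[later]:
                num += 1
            elif risk[first] == risk[later]:
                num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


def ssgsea_running_sum(values: dict[str, float], gene_set, alpha: float) -> float:
    """Naive per-sample ssGSEA score: walk the descending ranking and
    accumulate the weighted in-set ECDF minus the uniform out-of-set ECDF."""
    genes = list(values)
    n = len(genes)
    # average ranks, highest expression = largest rank
    order_asc = sorted(genes, key=lambda g: values[g])
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order_asc[j + 1]] == values[order_asc[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order_asc[k]] = avg
        i = j + 1
    walk = sorted(genes, key=lambda g: -values[g])
    in_set = set(g.upper() for g in gene_set)
    total_w = sum(ranks[g] ** alpha for g in walk if g.upper() in in_set)
    n_out = n - sum(1 for g in walk if g.upper() in in_set)
    cdf_in = cdf_out = score = 0.0
    for g in walk:
        if g.upper() in in_set:
            cdf_in += ranks[g] ** alpha / total_w
        else:
            cdf_out += 1.0 / n_out
        score += cdf_in - cdf_out
    return score
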