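"""Independent brute-force oracles used to pin the statistical primitives.

Everything here is enumeration or closed form built from combinatorics only —
no calls into the code paths under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.optimize import brentq


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities of all tables
    with the observed margins whose probability <= that of the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    probs = [comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-10)))


def conditional_or_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Conditional-MLE odds ratio: the noncentrality psi at which the observed
    count equals the mean of Fisher's noncentral hypergeometric distribution,
    found by root-finding over the enumerated support."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if lo == hi:
        return float("nan")
    if a == hi:
        return float("inf")
    if a == lo:
        return 0.0
    support = np.arange(lo, hi + 1)
    logw = np.array([np.log(comb(r1, int(x))) + np.log(comb(r2, int(c1 - x)))
                     for x in support])

    def mean_minus_a(log_psi: float) -> float:
        t = logw + support * log_psi
        t = np.exp(t - t.max())
        t /= t.sum()
        return float((support * t).sum()) - a

    return float(np.exp(brentq(mean_minus_a, -50.0, 50.0, xtol=1e-12)))


def ranksum_p_enumeration(x: list[float], y: list[float]) -> float:
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled values into two groups of the observed sizes (tie-free data)."""
    pooled = sorted(x + y)
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    mu = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for subset in combinations(pooled, n1):
        total += 1
        w = sum(ranks[v] for v in subset)
        if abs(w - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


def es_brute_force(metric: np.ndarray, member_mask: np.ndarray,
                   weight: float = 1.0) -> float:
    """Plain-loop weighted KS enrichment score."""
    n = len(metric)
    m = int(member_mask.sum())
    hit_total = sum(abs(metric[i]) ** weight for i in range(n) if member_mask[i])
    running = 0.0
    hi = lo = 0.0
    for i in range(n):
        if member_mask[i]:
            running += ((abs(metric[i]) ** weight) / hit_total
                        if hit_total > 0 else 1.0 / m)
        else:
            running -= 1.0 / (n - m)
        hi = max(hi, running)
        lo = min(lo, running)
    # same magnitude tie-break as the implementation: positive wins
    return hi if hi >= abs(lo) - 1e-12 else lo


def bh_step_up(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values straight from the definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_end in range(n, 0, -1):
        i = order[rank_from_end - 1]
        value = min(1.0, pvals[i] * n / rank_from_end)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def km_survival_no_censoring(times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Empirical survival function S(t) = P(T > t); equals KM when no one is
    censored."""
    return np.array([(times > t).mean() for t in grid])


def logrank_oe(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square from the observed-minus-expected table."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    all_times = np.unique(np.concatenate([times_a[events_a == 1],
                                          times_b[events_b == 1]]))
    O = E = V = 0.0
    for t in all_times:
        n1 = float((times_a >= t).sum())
        n2 = float((times_b >= t).sum())
        n = n1 + n2
        d = float(((times_a == t) & (events_a == 1)).sum()
                  + ((times_b == t) & (events_b == 1)).sum())
        d1 = float(((times_a == t) & (events_a == 1)).sum())
        if n < 2:
            continue
        O += d1
        E += d * n1 / n
        V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return (O - E) ** 2 / V if V > 0 else 0.0
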