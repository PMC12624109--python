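"""Brute-force reference implementations, kept independent of the package.

Used only to cross-check the library's statistics on small instances.
"""

from itertools import combinations

import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted p-values straight from the step-up
    definition: q_(i) = min over j >= i of p_(j) * n / j."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(n)
    running = np.inf
    for rank in range(n - 1, -1, -1):
        running = min(running, p[order[rank]] * n / (rank + 1))
        adj_sorted[rank] = min(running, 1.0)
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def pearson_r2(a, b):
    """Squared Pearson correlation from raw sums."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    num = n * np.sum(a * b) - np.sum(a) * np.sum(b)
    den = (n * np.sum(a * a) - np.sum(a) ** 2) * (n * np.sum(b * b) - np.sum(b) ** 2)
    return num * num / den


def mannwhitney_u(x, y):
    """U statistic of sample x by direct pair counting (ties count 1/2)."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u


def mannwhitney_exact_p(x, y):
    """Exact two-sided p by enumerating every assignment of the pooled
    sample into groups (assumes no ties across groups)."""
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = mannwhitney_u(x, y)
    centre = n * len(y) / 2.0
    hits = total = 0
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = mannwhitney_u(xs, ys)
        total += 1
        if abs(u - centre) >= abs(u_obs - centre) - 1e-12:
            hits += 1
    return hits / total
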