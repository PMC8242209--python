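"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries) they check:
rank statistics are computed by exhaustive pair counting / hand-rolled
mid-ranks, and the through-origin slope by iterative grid search over the
residual sum of squares.
"""

from __future__ import annotations

import math


def midranks(values):
    """Mid-ranks (average rank for ties), 1-based, by explicit sorting."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_oracle(a, b):
    """Spearman rho as Pearson on mid-ranks."""
    return pearson(midranks(list(a)), midranks(list(b)))


def kendall_tau_b_oracle(a, b):
    """Kendall tau-b by exhaustive concordant/discordant pair counting."""
    n = len(a)
    concordant = discordant = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da = a[i] - a[j]
            db = b[i] - b[j]
            if da == 0 and db == 0:
                continue
            if da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    # pairs tied in a (including double ties) / in b
    ta = sum(1 for i in range(n) for j in range(i + 1, n) if a[i] == a[j])
    tb = sum(1 for i in range(n) for j in range(i + 1, n) if b[i] == b[j])
    return (concordant - discordant) / math.sqrt((n0 - ta) * (n0 - tb))


def grid_search_slope(conc, ratio, lo=-200.0, hi=200.0, rounds=4, points=2001):
    """Brute-force minimizer of sum((ratio-1) - slope*c)^2 over a shrinking
    grid of candidate slopes; converges well below 1e-6 in 4 rounds."""

    def rss(slope):
        return sum(((r - 1.0) - slope * c) ** 2 for c, r in zip(conc, ratio))

    for _ in range(rounds):
        step = (hi - lo) / (points - 1)
        best = min((lo + k * step for k in range(points)), key=rss)
        lo, hi = best - step, best + step
    return best
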