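"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the library code paths (and scipy shortcuts where
feasible) so that agreement is informative: exact rational enumeration for
the binomial and Fisher tests, direct summation for the hypergeometric
tail, a literal step-up loop for BH, and the rank-sum formula for
Kruskal-Wallis.
"""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np


def binom_two_sided_enum(n: int, k: int) -> float:
    """Central two-sided binomial p at p0=1/2 by enumerating all 2^n outcomes."""
    counts = [0] * (n + 1)
    for outcome in product([0, 1], repeat=n):
        counts[sum(outcome)] += 1
    total = 2**n
    lower = Fraction(sum(counts[: k + 1]), total)
    upper = Fraction(sum(counts[k:]), total)
    return float(min(Fraction(1), 2 * min(lower, upper)))


def fisher_two_sided_enum(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration over the margin.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table (exact rational
    arithmetic).
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> Fraction:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    return float(sum(p for x in range(0, min(r1, c1) + 1)
                     if (p := prob(x)) <= p_obs))


def hypergeom_tail_sum(universe: int, n_marked: int, n_drawn: int, k: int) -> float:
    """P(X >= k) by direct summation of hypergeometric probabilities."""
    total = comb(universe, n_drawn)
    s = sum(
        Fraction(comb(n_marked, x) * comb(universe - n_marked, n_drawn - x), total)
        for x in range(k, min(n_marked, n_drawn) + 1)
    )
    return float(s)


def bh_stepup(pvals):
    """Literal BH step-up: find the largest i with p_(i) <= i/m * alpha is
    equivalent to adjusted p_(i) = min over j>=i of m*p_(j)/j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


def kruskal_h(groups) -> float:
    """Kruskal-Wallis H from the rank-sum formula with tie correction."""
    from scipy.stats import rankdata

    all_vals = np.concatenate(groups)
    ranks = rankdata(all_vals)
    n = len(all_vals)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


def auc_trapezoid(scores, labels) -> float:
    """AUC by trapezoidal integration of the empirical ROC (tie-free scores)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(-scores)
    y = y[order]
    tp = np.concatenate([[0], np.cumsum(y == 1)])
    fp = np.concatenate([[0], np.cumsum(y == 0)])
    tpr = tp / max(tp[-1], 1)
    fpr = fp / max(fp[-1], 1)
    return float(np.trapezoid(tpr, fpr))
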