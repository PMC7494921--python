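"""Independent brute-force oracles used only by the tests.

Each function recomputes a quantity from its textbook definition, by direct
enumeration or explicit loops, deliberately avoiding the code paths (and
where possible the libraries) used by the implementation.
"""

from __future__ import annotations

import math

import numpy as np


def tensor_collapse_loop(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Explicitly form the 3-way tensor x_ijk = a_ij * b_kj and sum over j."""
    n, m = a.shape
    k, m2 = b.shape
    assert m == m2
    out = np.zeros((n, k))
    for i in range(n):
        for j in range(m):
            for kk in range(k):
                out[i, kk] += a[i, j] * b[kk, j]
    return out


def bh_bruteforce(p) -> np.ndarray:
    """O(m^2) Benjamini-Hochberg from the step-up definition: the adjusted
    value of p_i is min over all p_j >= p_i of m * p_j / rank(p_j), capped
    at 1, with rank(p_j) = #{q <= p_j}."""
    p = list(map(float, p))
    m = len(p)
    adj = []
    for pi in p:
        cands = [
            m * pj / sum(1 for q in p if q <= pj)
            for pj in p
            if pj >= pi
        ]
        adj.append(min(1.0, min(cands)))
    return np.array(adj)


def chi2_1_sf(x: float) -> float:
    """Upper tail of chi-squared with 1 df, via the closed form
    P[chi2_1 > x] = erfc(sqrt(x / 2))."""
    return math.erfc(math.sqrt(x / 2.0))


def hypergeom_pmf(x: int, r1: int, c1: int, n: int) -> float:
    """P[top-left cell = x] for a 2x2 table with row-1 margin r1, column-1
    margin c1 and total n."""
    return (
        math.comb(c1, x)
        * math.comb(n - c1, r1 - x)
        / math.comb(n, r1)
    )


def fisher_twosided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P by full enumeration of the hypergeometric
    support: sum of probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (with a tiny
    relative slack for float ties)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    p_obs = hypergeom_pmf(a, r1, c1, n)
    total = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom_pmf(x, r1, c1, n)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


def welch_p_scalar(x, y) -> float:
    """Two-sided Welch t-test P from the textbook statistic and the
    Welch-Satterthwaite degrees of freedom."""
    import scipy.stats

    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2 * scipy.stats.t.sf(abs(t), df)
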