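"""Independent numerical oracles used to cross-check the implementation.

Each oracle computes the same quantity as the production code by a
different route (direct integration, exhaustive enumeration, explicit
loops), so agreement is evidence of correctness rather than repetition.
"""

import math

import numpy as np
from scipy.integrate import quad


def t_two_sided_p(t_stat: float, df: int) -> float:
    """Two-sided t-test p-value by numerical integration of the t density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def dens(u):
        return c * (1.0 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = quad(dens, abs(t_stat), np.inf)
    return min(2.0 * tail, 1.0)


def tom_triple_loop(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap by explicit triple loops (no matrix algebra)."""
    A = adjacency.copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = 0.0
            for u in range(n):
                if u != i and u != j:
                    l_ij += A[i, u] * A[u, j]
            k_i = sum(A[i, u] for u in range(n) if u != i)
            k_j = sum(A[j, u] for u in range(n) if u != j)
            tom[i, j] = (l_ij + A[i, j]) / (min(k_i, k_j) + 1.0 - A[i, j])
    return tom


def fisher_two_sided_p(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums the point probabilities of every table with the observed margins
    whose probability does not exceed the observed table's.
    """
    row1 = n11 + n10
    col1 = n11 + n01
    total = n11 + n10 + n01 + n00

    def prob(k):
        return (
            math.comb(col1, k)
            * math.comb(total - col1, row1 - k)
            / math.comb(total, row1)
        )

    p_obs = prob(n11)
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Direct BH adjustment (step-up), written independently."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        adjusted[idx] = val
        prev = val
    return adjusted
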