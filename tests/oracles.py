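"""Independent brute-force oracles used across the test suite.

Everything here is exact-fraction or direct-linear-algebra arithmetic,
deliberately sharing no code path with the package implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_tail_exact(i: int, population: int, successes: int,
                         draws: int) -> Fraction:
    """Exact P(X >= i) for a hypergeometric, by summing point masses."""
    denom = comb(population, draws)
    total = Fraction(0)
    upper = min(successes, draws)
    for k in range(max(i, 0), upper + 1):
        total += Fraction(comb(successes, k) * comb(population - successes,
                                                    draws - k), denom)
    return total


def fisher_tail_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Over-representation tail of [[a, b], [c, d]] by table enumeration."""
    return hypergeom_tail_exact(a, a + b + c + d, a + b, a + c)


def min_hypergeom_exact(member_pvalues, all_pvalues) -> Fraction:
    """Exhaustive minimum-hypergeometric p-value for a ranked gene set.

    ``member_pvalues`` are the set members' per-gene p-values;
    ``all_pvalues`` the whole ranked list's.  Every member threshold is
    enumerated and its tail summed exactly.
    """
    all_p = sorted(all_pvalues)
    member_p = sorted(member_pvalues)
    l, s = len(all_p), len(member_p)
    best = Fraction(1)
    for i, mp in enumerate(member_p, start=1):
        l_i = sum(1 for p in all_p if p <= mp)
        tail = hypergeom_tail_exact(i, l, s, l_i)
        best = min(best, tail)
    return best


def pagerank_linear_solve(edges, n: int, damping: float = 0.85) -> np.ndarray:
    """PageRank by direct solution of the stationary linear system.

    Nodes are 0..n-1; dangling nodes link uniformly to every node.
    """
    out_deg = np.zeros(n)
    for u, _ in edges:
        out_deg[u] += 1
    m = np.zeros((n, n))
    for u, v in edges:
        m[v, u] += 1.0 / out_deg[u]
    for u in range(n):
        if out_deg[u] == 0:
            m[:, u] = 1.0 / n
    a = np.eye(n) - damping * m
    b = np.full(n, (1 - damping) / n)
    return np.linalg.solve(a, b)


def holm_reference(pvalues) -> np.ndarray:
    """Holm step-down adjustment by the textbook formula."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
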