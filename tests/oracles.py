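"""Independent brute-force reference implementations used only by the tests.

These deliberately use naive loops and textbook formulas, sharing no code with
the package, so that agreement is evidence of correctness rather than of
shared bugs.
"""

from __future__ import annotations

import numpy as np


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """BH step-up by direct enumeration: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = []
        for rank_j in range(rank_i, m + 1):
            pj = p[order[rank_j - 1]]
            candidates.append(min(1.0, pj * m / rank_j))
        q[idx] = min(candidates)
    return q


def midrank(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mid-rank."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    ranks = np.empty(n)
    for i in range(n):
        less = np.sum(x < x[i])
        equal = np.sum(x == x[i])
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks, computed from the definition."""
    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def concordance_bruteforce(e: np.ndarray, d: np.ndarray) -> tuple[int, int]:
    """(Np, Nt) by explicit loop; strict positivity, zero products excluded from Np."""
    np_ = 0
    nt = 0
    for a, b in zip(e, d):
        nt += 1
        if a * b > 0:
            np_ += 1
    return np_, nt


def nb_moments(mean: float, alpha: float) -> tuple[float, float]:
    """Mean and variance of NB in the var = mu + alpha mu^2 parameterization."""
    return mean, mean + alpha * mean**2
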