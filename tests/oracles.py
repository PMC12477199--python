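"""Independent brute-force oracles used to cross-check the implementation."""

import itertools
from fractions import Fraction

import numpy as np


def brute_force_wcss(points: np.ndarray, k: int) -> float:
    """Exhaustive minimum within-cluster sum of squares over all
    assignments of n points into at most k clusters."""
    n = len(points)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        wcss = 0.0
        for c in range(k):
            members = points[[i for i in range(n) if assign[i] == c]]
            if len(members):
                wcss += float(((members - members.mean(axis=0)) ** 2).sum())
        best = min(best, wcss)
    return best


def hypergeom_overlap_distribution(K: int, n: int, N: int) -> dict[int, Fraction]:
    """Exact overlap distribution by enumerating all C(N, n) draws from a
    population of N items of which the first K are marked."""
    counts: dict[int, int] = {}
    total = 0
    marked = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        k = len(marked.intersection(draw))
        counts[k] = counts.get(k, 0) + 1
    return {k: Fraction(c, total) for k, c in counts.items()}


def hypergeom_tail_by_enumeration(k: int, K: int, n: int, N: int) -> Fraction:
    dist = hypergeom_overlap_distribution(K, n, N)
    return sum((p for kk, p in dist.items() if kk >= k), Fraction(0))
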