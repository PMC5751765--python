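"""Shared test oracles: naive pair-counting scores and set-partition enumeration."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def naive_rand(a, b) -> float:
    """O(n^2) pair enumeration Rand score."""
    a = np.asarray(a)
    b = np.asarray(b)
    agree = 0
    pairs = list(combinations(range(len(a)), 2))
    for i, j in pairs:
        if (a[i] == a[j]) == (b[i] == b[j]):
            agree += 1
    return agree / len(pairs)


def naive_ari(a, b) -> float:
    """Hypergeometric-adjusted Rand from explicit pair counts."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    s_ij = sum(1 for i, j in combinations(range(n), 2) if a[i] == a[j] and b[i] == b[j])
    s_a = sum(1 for i, j in combinations(range(n), 2) if a[i] == a[j])
    s_b = sum(1 for i, j in combinations(range(n), 2) if b[i] == b[j])
    total = comb(n, 2)
    expected = s_a * s_b / total
    denom = 0.5 * (s_a + s_b) - expected
    if denom == 0:
        return 1.0 if s_ij == expected else 0.0
    return (s_ij - expected) / denom


def set_partitions(n: int):
    """All partitions of n items as restricted-growth label vectors."""
    labels = [0] * n

    def rec(i: int, maxused: int):
        if i == n:
            yield tuple(labels)
            return
        for v in range(maxused + 2):
            labels[i] = v
            yield from rec(i + 1, max(maxused, v))

    yield from rec(0, -1)
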