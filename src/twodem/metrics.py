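"""Clustering agreement scores: Rand score and adjusted Rand index.

Both are computed from the r x s contingency table of two partitions using
exact Python integer arithmetic for all pair counts, so results are exact at
any n.  The Rand score is the fraction of sample pairs on which the two
partitions agree (co-clustered in both or separated in both).  The adjusted
Rand index subtracts the agreement expected by chance under the generalized
hypergeometric model with fixed marginals; it is 0 in expectation for
independent partitions and 1 for identical ones, and can go negative.
"""

from __future__ import annotations

from math import comb

import numpy as np

__all__ = ["contingency_table", "rand_index", "adjusted_rand_index"]


def _as_labels(a) -> np.ndarray:
    arr = np.asarray(getattr(a, "labels", a))
    if arr.ndim != 1:
        raise ValueError("labels must be 1-D")
    return arr


def contingency_table(a, b) -> np.ndarray:
    """Co-occurrence counts n_ij between the clusters of two partitions."""
    a = _as_labels(a)
    b = _as_labels(b)
    if a.size != b.size:
        raise ValueError(f"partition lengths differ: {a.size} vs {b.size}")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    r, s = ai.max() + 1, bi.max() + 1
    table = np.zeros((r, s), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def _pair_counts(table: np.ndarray) -> tuple[int, int, int, int]:
    """(sum_ij C(n_ij,2), sum_i C(a_i,2), sum_j C(b_j,2), C(n,2)) as exact ints."""
    n = int(table.sum())
    s_ij = sum(comb(int(x), 2) for x in table.ravel())
    s_a = sum(comb(int(x), 2) for x in table.sum(axis=1))
    s_b = sum(comb(int(x), 2) for x in table.sum(axis=0))
    return s_ij, s_a, s_b, comb(n, 2)


def rand_index(a, b) -> float:
    """Fraction of pairs co-clustered in both or separated in both; in [0, 1]."""
    table = contingency_table(a, b)
    if table.sum() < 2:
        raise ValueError("need at least 2 samples")
    s_ij, s_a, s_b, total = _pair_counts(table)
    # agreements = both-together + both-apart
    agree = total + 2 * s_ij - s_a - s_b
    return agree / total


def adjusted_rand_index(a, b) -> float:
    """Rand agreement corrected for chance; 1 for identical partitions.

    ARI = (sum_ij C(n_ij,2) - E) / (0.5*(sum_i C(a_i,2) + sum_j C(b_j,2)) - E)
    with E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2).  When the denominator
    vanishes (both partitions all-singleton or both one block) the index is
    1.0 if the partitions are identical as partitions and 0.0 otherwise.
    """
    table = contingency_table(a, b)
    if table.sum() < 2:
        raise ValueError("need at least 2 samples")
    s_ij, s_a, s_b, total = _pair_counts(table)
    # exact rational arithmetic: multiply through by 2*C(n,2)
    num = 2 * (s_ij * total - s_a * s_b)
    den = (s_a + s_b) * total - 2 * s_a * s_b
    if den == 0:
        # degenerate marginals; identical partitions score 1 by convention
        return 1.0 if num == 0 and _same_partition(table) else 0.0
    return num / den


def _same_partition(table: np.ndarray) -> bool:
    """True when the contingency table encodes one partition twice."""
    return int((table > 0).sum()) == max(table.shape) and table.shape[0] == table.shape[1]
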