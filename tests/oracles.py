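"""Independent oracles used by the test suite.

These are deliberately separate implementations from the package:
a full-matrix Gotoh local-alignment scorer (numba-compiled) and a
brute-force quartet evaluator for neighbor joining.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _gotoh_local_score(a, b, match, mismatch, gap_open, gap_extend):
    n, m = len(a), len(b)
    NEG = -10**9
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (left)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (up)
    best = 0
    first_gap = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - gap_extend, H[i, j - 1] - first_gap)
            F[i, j] = max(F[i - 1, j] - gap_extend, H[i - 1, j] - first_gap)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def local_alignment_score(a: str, b: str, match=1, mismatch=-1,
                          gap_open=2, gap_extend=1) -> int:
    """Optimal Smith-Waterman score with affine gaps (gap of length L
    costs gap_open + L * gap_extend), by full-matrix DP."""
    ax = np.frombuffer(a.encode(), dtype=np.uint8)
    bx = np.frombuffer(b.encode(), dtype=np.uint8)
    return int(
        _gotoh_local_score(ax, bx, match, mismatch, gap_open, gap_extend)
    )


def quartet_splits(labels, dist):
    """Evaluate the three possible quartet splits of four taxa under the
    four-point condition; returns the splits sorted by their induced
    internal branch length (largest = the additive split)."""
    a, b, c, d = labels
    # four-point condition: the two largest pair sums are equal and the
    # split corresponding to the SMALLEST sum is the true one
    pair_sums = [
        (dist(a, b) + dist(c, d), frozenset([frozenset([a, b]),
                                             frozenset([c, d])])),
        (dist(a, c) + dist(b, d), frozenset([frozenset([a, c]),
                                             frozenset([b, d])])),
        (dist(a, d) + dist(b, c), frozenset([frozenset([a, d]),
                                             frozenset([b, c])])),
    ]
    pair_sums.sort(key=lambda t: t[0])
    return pair_sums
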