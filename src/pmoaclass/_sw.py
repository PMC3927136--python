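"""Affine-gap local alignment kernel (Smith–Waterman) used by the search engine.

The kernel computes the full dynamic-programming matrices so the reported raw
score is exactly optimal under the configured scoring scheme; seeding (in
:mod:`pmoaclass.search`) decides *which* pairs are aligned, not how far an
alignment extends.  Gap costs follow the BLAST convention: a gap of length L
costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG = -(10**9)


@njit(cache=False)
def _affine_sw_matrices(a, b, submat, gap_open, gap_extend):
    m = a.size
    n = b.size
    H = np.zeros((m + 1, n + 1), np.int64)
    E = np.full((m + 1, n + 1), _NEG, np.int64)
    F = np.full((m + 1, n + 1), _NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_open - gap_extend
            e2 = E[i, j - 1] - gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - gap_open - gap_extend
            f2 = F[i - 1, j] - gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + submat[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, H, E, F


def affine_local_align(
    a: np.ndarray,
    b: np.ndarray,
    submat: np.ndarray,
    gap_open: int,
    gap_extend: int,
) -> tuple[int, tuple[int, int], tuple[int, int], list[tuple[int, int]]]:
    """Optimal local alignment of integer-encoded sequences ``a`` vs ``b``.

    Returns ``(score, a_span, b_span, pairs)`` where spans are 1-based inclusive
    and ``pairs`` lists aligned index pairs ``(i, j)`` with 0 marking a gap
    (1-based positions otherwise).  An empty alignment (score 0) yields empty
    spans.  Ties in the traceback prefer substitution over gaps, so output is
    deterministic.
    """
    best, bi, bj, H, E, F = _affine_sw_matrices(
        a, b, submat, np.int64(gap_open), np.int64(gap_extend)
    )
    if best <= 0:
        return 0, (0, 0), (0, 0), []

    pairs: list[tuple[int, int]] = []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + submat[a[i - 1], b[j - 1]]
            if H[i, j] == diag:
                pairs.append((i, j))
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            pairs.append((0, j))
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = "H"
            j -= 1
        else:
            pairs.append((i, 0))
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = "H"
            i -= 1
    pairs.reverse()
    a_span = (i + 1, bi)
    b_span = (j + 1, bj)
    return int(best), a_span, b_span, pairs


def best_local_score(
    a: np.ndarray, b: np.ndarray, submat: np.ndarray, gap_open: int, gap_extend: int
) -> int:
    """Score-only variant of :func:`affine_local_align`."""
    best, _, _, _, _, _ = _affine_sw_matrices(
        a, b, submat, np.int64(gap_open), np.int64(gap_extend)
    )
    return int(best)
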