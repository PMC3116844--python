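"""Numba-jitted affine-gap dynamic-programming kernels.

Both kernels score a query index vector against a positional profile matrix
``prof`` of shape (m, 21): columns 0..19 follow RESIDUE_ORDER, column 20 is
the score of an unknown ('X') query residue against that position. A gap of
length k costs ``gap_open + k * gap_extend`` (EMBOSS convention), and
gap-state switches (a deletion run directly followed by an insertion run)
open a fresh gap, so the kernels are exact over the space of all gapped
alignments.

Pointer codes: 0 = from M (diagonal), 1 = from Ix (gap in subject, consumes
query), 2 = from Iy (gap in query, consumes subject), 3 = local start.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def global_affine(q, prof, gap_open, gap_extend):
    n = q.shape[0]
    m = prof.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), np.uint8)
    pX = np.zeros((n + 1, m + 1), np.uint8)
    pY = np.zeros((n + 1, m + 1), np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + i * gap_extend)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + j * gap_extend)
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = prof[j - 1, qi]
            best = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p

            best = M[i - 1, j] - gap_open - gap_extend
            p = 0
            v = Ix[i - 1, j] - gap_extend
            if v > best:
                best = v
                p = 1
            v = Iy[i - 1, j] - gap_open - gap_extend
            if v > best:
                best = v
                p = 2
            Ix[i, j] = best
            pX[i, j] = p

            best = M[i, j - 1] - gap_open - gap_extend
            p = 0
            v = Ix[i, j - 1] - gap_open - gap_extend
            if v > best:
                best = v
                p = 1
            v = Iy[i, j - 1] - gap_extend
            if v > best:
                best = v
                p = 2
            Iy[i, j] = best
            pY[i, j] = p
    return M, Ix, Iy, pM, pX, pY


@njit(cache=True)
def local_affine(q, prof, gap_open, gap_extend):
    """Smith–Waterman with affine gaps; alignments start and end on a match."""
    n = q.shape[0]
    m = prof.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), np.uint8)
    pX = np.zeros((n + 1, m + 1), np.uint8)
    pY = np.zeros((n + 1, m + 1), np.uint8)
    best_score = 0.0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = prof[j - 1, qi]
            best = 0.0
            p = 3
            if M[i - 1, j - 1] > best:
                best = M[i - 1, j - 1]
                p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p
            if M[i, j] > best_score:
                best_score = M[i, j]
                best_i = i
                best_j = j

            best = M[i - 1, j] - gap_open - gap_extend
            p = 0
            v = Ix[i - 1, j] - gap_extend
            if v > best:
                best = v
                p = 1
            v = Iy[i - 1, j] - gap_open - gap_extend
            if v > best:
                best = v
                p = 2
            Ix[i, j] = best
            pX[i, j] = p

            best = M[i, j - 1] - gap_open - gap_extend
            p = 0
            v = Ix[i, j - 1] - gap_open - gap_extend
            if v > best:
                best = v
                p = 1
            v = Iy[i, j - 1] - gap_extend
            if v > best:
                best = v
                p = 2
            Iy[i, j] = best
            pY[i, j] = p
    return M, Ix, Iy, pM, pX, pY, best_score, best_i, best_j
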