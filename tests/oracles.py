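"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's dynamic-programming kernels:
``enumerate_global`` walks every gapped alignment explicitly, and
``local_recursive`` is a memoized recursion over (i, j, gap-state) written
directly from the definition of a local alignment. ``roc_by_enumeration``
sweeps every distinct score as a threshold.
"""

from __future__ import annotations

import math
import sys
from functools import lru_cache

import numpy as np


def enumerate_global(n: int, m: int, pair_score, gap_open: float, gap_extend: float) -> float:
    """Best global alignment score by explicit enumeration of all alignments.

    ``pair_score(i, j)`` scores query position i against subject position j
    (0-based). A maximal gap run of length k costs gap_open + k*gap_extend.
    Exponential: use only for n, m <= 8.
    """
    best = -math.inf

    def rec(i: int, j: int, acc: float, state: int) -> None:
        nonlocal best
        if i == n and j == m:
            best = max(best, acc)
            return
        if i < n and j < m:
            rec(i + 1, j + 1, acc + pair_score(i, j), 0)
        if i < n:  # consume query, gap in subject
            cost = gap_extend + (gap_open if state != 1 else 0.0)
            rec(i + 1, j, acc - cost, 1)
        if j < m:  # consume subject, gap in query
            cost = gap_extend + (gap_open if state != 2 else 0.0)
            rec(i, j + 1, acc - cost, 2)

    rec(0, 0, 0.0, 0)
    return best


def local_recursive(n: int, m: int, pair_score, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score from the recursive definition, memoized.

    ``match(i, j)`` is the best score of an alignment ending with positions
    i/j matched (it may begin anywhere earlier); gap states carry the affine
    run cost. The overall optimum is the best match end, floored at 0.
    """
    sys.setrecursionlimit(100_000)

    @lru_cache(maxsize=None)
    def match(i: int, j: int) -> float:
        inner = max(0.0, match(i - 1, j - 1), gap_q(i - 1, j - 1), gap_s(i - 1, j - 1)) \
            if i > 0 and j > 0 else 0.0
        return pair_score(i, j) + inner

    @lru_cache(maxsize=None)
    def gap_q(i: int, j: int) -> float:
        # alignment ends by consuming query position i against a gap
        if i < 0 or j < 0:
            return -math.inf
        if i == 0:
            return -math.inf
        return max(
            match(i - 1, j) - gap_open - gap_extend,
            gap_q(i - 1, j) - gap_extend,
            gap_s(i - 1, j) - gap_open - gap_extend,
        )

    @lru_cache(maxsize=None)
    def gap_s(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return -math.inf
        if j == 0:
            return -math.inf
        return max(
            match(i, j - 1) - gap_open - gap_extend,
            gap_q(i, j - 1) - gap_open - gap_extend,
            gap_s(i, j - 1) - gap_extend,
        )

    best = 0.0
    for i in range(n):
        for j in range(m):
            best = max(best, match(i, j))
    return best


def local_by_substring_enumeration(
    n: int, m: int, pair_score, gap_open: float, gap_extend: float
) -> float:
    """Local optimum as the max global score over all substring pairs.

    Purely exhaustive; practical only for n, m <= ~5. Used to validate
    ``local_recursive`` itself.
    """
    best = 0.0
    for qs in range(n):
        for qe in range(qs + 1, n + 1):
            for ps in range(m):
                for pe in range(ps + 1, m + 1):
                    sub = enumerate_global(
                        qe - qs,
                        pe - ps,
                        lambda i, j: pair_score(qs + i, ps + j),
                        gap_open,
                        gap_extend,
                    )
                    best = max(best, sub)
    return best


def roc_by_enumeration(scores: np.ndarray, labels: np.ndarray):
    """(fpr, sensitivity) at every distinct threshold, plus trapezoidal AUC.

    Pairs scoring >= the threshold are predicted positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = labels.sum()
    neg = (~labels).sum()
    points = [(0.0, 0.0)]
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = (pred & labels).sum()
        fp = (pred & ~labels).sum()
        points.append((fp / neg, tp / pos))
    points.append((1.0, 1.0))
    pts = sorted(set(points))
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return pts, auc
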