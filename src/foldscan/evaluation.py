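"""Benchmarking statistics: ROC curves, top-k confusion sets, method
comparison, and cumulative distributions.

Ground truth is a same-fold / different-fold label per unordered query
pair. ROC analysis pools all pairs globally and sweeps a score threshold:
sensitivity = TP / (TP + FN), false-positive rate = FP / (FP + TN); pairs
scoring exactly at the threshold count as predicted positive. AUC is the
trapezoidal area. Top-k confusion mirrors the all-against-all protocol:
for each query the k best-scoring partners are predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class RankedPairTable:
    """All-against-all similarity scores plus same-fold truth labels.

    ``scores`` is symmetric with an arbitrary diagonal (self-pairs are
    excluded from every statistic). ``labels`` maps frozenset({a, b}) ->
    True for same-fold pairs.
    """

    ids: tuple[str, ...]
    scores: np.ndarray
    labels: dict | None = None

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        n = len(self.ids)
        if scores.shape != (n, n):
            raise ValueError("score matrix shape must match the id list")
        if not np.allclose(scores, scores.T):
            raise ValueError("score matrix must be symmetric")
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    def score(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.scores[ia, ib])

    def ranking(self, query: str) -> list[tuple[str, float]]:
        """Partners of ``query`` sorted by descending score, ties by id."""
        iq = self.ids.index(query)
        partners = [
            (other, float(self.scores[iq, j]))
            for j, other in enumerate(self.ids)
            if j != iq
        ]
        return sorted(partners, key=lambda t: (-t[1], t[0]))

    def pooled_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(scores, labels) over all unordered pairs; requires truth labels."""
        if self.labels is None:
            raise ValueError("table carries no truth labels")
        y, s = [], []
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                b = self.ids[j]
                y.append(bool(self.labels[frozenset((a, b))]))
                s.append(self.scores[i, j])
        return np.asarray(s, dtype=float), np.asarray(y, dtype=bool)


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def sensitivity_at(self, fpr_target: float) -> float:
        """Highest sensitivity among curve points with FPR <= fpr_target."""
        ok = self.fpr <= fpr_target
        return float(self.tpr[ok].max()) if ok.any() else 0.0


def roc_curve(table: RankedPairTable) -> ROCCurve:
    """ROC over globally pooled pairs, with trapezoidal AUC.

    Raises when the table has no positive or no negative pairs (the curve
    is undefined).
    """
    scores, labels = table.pooled_pairs()
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("ROC requires at least one positive and one negative pair")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


@dataclass(frozen=True)
class TopKConfusion:
    """Per-query top-k prediction outcome, as (query, partner) pair sets."""

    tp: frozenset
    fp: frozenset
    fn: frozenset

    def unordered(self, category: str) -> frozenset:
        return frozenset(frozenset(p) for p in getattr(self, category))


def topk_confusion(table: RankedPairTable, k: int = 9) -> TopKConfusion:
    """Classify each query's top-k ranked partners against the fold labels.

    Same-fold partners inside the top k are TP, different-fold partners
    inside are FP, and same-fold partners left outside are FN. With fewer
    than k partners available, all of them are considered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if table.labels is None:
        raise ValueError("table carries no truth labels")
    tp, fp, fn = set(), set(), set()
    for query in table.ids:
        ranking = table.ranking(query)
        top = ranking[:k]
        rest = ranking[k:]
        for partner, _ in top:
            if table.labels[frozenset((query, partner))]:
                tp.add((query, partner))
            else:
                fp.add((query, partner))
        for partner, _ in rest:
            if table.labels[frozenset((query, partner))]:
                fn.add((query, partner))
    return TopKConfusion(frozenset(tp), frozenset(fp), frozenset(fn))


def compare_methods(confusions: dict[str, TopKConfusion]) -> dict:
    """Shared / unique pair counts per category across named methods.

    Pairs are compared as unordered id pairs. Returns, per category, each
    method's total, every pairwise intersection size, and each method's
    count of pairs found by no other method.
    """
    if len(confusions) < 2:
        raise ValueError("compare_methods requires >= 2 methods")
    names = sorted(confusions)
    report: dict = {}
    for category in ("tp", "fp", "fn"):
        sets = {m: confusions[m].unordered(category) for m in names}
        entry = {
            "sizes": {m: len(sets[m]) for m in names},
            "shared": {},
            "unique": {},
        }
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                entry["shared"][(a, b)] = len(sets[a] & sets[b])
        for m in names:
            others = set().union(*(sets[o] for o in names if o != m))
            entry["unique"][m] = len(sets[m] - others)
        report[category] = entry
    return report


@dataclass(frozen=True)
class EmpiricalCDF:
    """Empirical CDF of a score or identity sample."""

    values: np.ndarray  # sorted
    cumulative: np.ndarray  # P(X <= value), non-decreasing, ends at 1

    def fraction_above(self, threshold: float) -> float:
        """Fraction of the sample strictly greater than ``threshold``."""
        return float(np.mean(self.values > threshold))

    def fraction_at_or_below(self, threshold: float) -> float:
        return float(np.mean(self.values <= threshold))


def cumulative_distribution(
    values, thresholds: tuple[float, ...] = ()
) -> tuple[EmpiricalCDF, dict[float, float]]:
    """ECDF of ``values`` plus fraction-above reports at the given thresholds."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("cumulative_distribution requires a non-empty sample")
    cdf = EmpiricalCDF(values=arr, cumulative=np.arange(1, arr.size + 1) / arr.size)
    return cdf, {t: cdf.fraction_above(t) for t in thresholds}
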