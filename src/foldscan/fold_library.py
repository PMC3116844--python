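"""Construction of fold-specific PSSM libraries from fold-labeled sequence sets.

A fold library is one PSSM per seed (reference) sequence, built from the
seed plus a set of pre-collected homologs. Homolog acquisition (e.g. a
PSI-BLAST expansion against NR) is an input step: this module accepts the
sequence sets from any source, applies the redundancy filters, and turns
each set into a position-specific log-odds matrix.

PSSM model
----------
Homologs are placed on seed columns by global alignment to the seed. Observed
column frequencies are weighted with Henikoff position-based sequence
weights, then mixed with substitution-matrix-derived pseudocounts:

    q_j = (alpha_j * f_j + beta * g_j) / (alpha_j + beta)

where f_j are the weighted observed frequencies at column j, g_j(r) =
sum_a f_j(a) * T(r | a) with T the BLOSUM-derived conditional substitution
probabilities, alpha_j = (distinct residue types at column j) - 1, and beta
is the single tunable pseudocount weight (default 10). Scores are
2 * log2(q_j(r) / p(r)) in half-bit units — the same scale as integer
BLOSUM62 — rounded to 2 decimals, with Robinson–Robinson background p.

T is balanced (Sinkhorn) so that its stationary distribution is exactly the
background: a column observed at background frequencies therefore scores
zero everywhere, and with no homologs at all each column reduces to
(approximately) the BLOSUM62 row of the seed residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pairwise_align import global_align, percent_identity
from .seq_formats import (
    RESIDUE_INDEX,
    RESIDUE_ORDER,
    PSSMRecord,
    SequenceRecord,
    SubstitutionMatrix,
    read_collection_manifest,
    read_pssm,
    write_collection_manifest,
    write_pssm,
)

#: Robinson–Robinson amino-acid background frequencies, RESIDUE_ORDER order.
ROBINSON_BACKGROUND = np.array(
    [
        0.07805, 0.05129, 0.04487, 0.05364, 0.01925,  # A R N D C
        0.04264, 0.06295, 0.07377, 0.02199, 0.05142,  # Q E G H I
        0.09019, 0.05744, 0.02243, 0.03856, 0.05203,  # L K M F P
        0.07120, 0.05841, 0.01330, 0.03216, 0.06441,  # S T W Y V
    ]
)
ROBINSON_BACKGROUND = ROBINSON_BACKGROUND / ROBINSON_BACKGROUND.sum()


@dataclass
class FoldLibrary:
    """A named set of PSSMs for one fold."""

    fold_id: str
    pssms: list[PSSMRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.pssms:
            raise ValueError(f"fold library {self.fold_id!r} requires >= 1 PSSM")
        ids = [p.id for p in self.pssms]
        if len(set(ids)) != len(ids):
            raise ValueError(f"fold library {self.fold_id!r} has duplicate PSSM ids")

    def __len__(self) -> int:
        return len(self.pssms)

    @property
    def total_columns(self) -> int:
        return sum(len(p) for p in self.pssms)


@dataclass
class LibraryCollection:
    """An ordered set of fold libraries; the order defines profile vector axes."""

    libraries: list[FoldLibrary]

    def __post_init__(self):
        ids = [lib.fold_id for lib in self.libraries]
        if len(set(ids)) != len(ids):
            dup = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate fold ids in collection: {dup}")

    @property
    def fold_ids(self) -> tuple[str, ...]:
        return tuple(lib.fold_id for lib in self.libraries)

    def __len__(self) -> int:
        return len(self.libraries)

    def __iter__(self):
        return iter(self.libraries)

    def save(self, directory: str | Path) -> None:
        """Write one PSSM text file per member plus a manifest fixing axis order."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for lib in self.libraries:
            for pssm in lib.pssms:
                rel = f"{lib.fold_id}__{pssm.id}.pssm"
                write_pssm(pssm, directory / rel)
                entries.append((lib.fold_id, rel))
        write_collection_manifest(entries, directory / "manifest.tsv")

    @classmethod
    def load(cls, directory: str | Path) -> "LibraryCollection":
        directory = Path(directory)
        entries = read_collection_manifest(directory / "manifest.tsv")
        by_fold: dict[str, list[PSSMRecord]] = {}
        order: list[str] = []
        for fold_id, rel in entries:
            if fold_id not in by_fold:
                by_fold[fold_id] = []
                order.append(fold_id)
            by_fold[fold_id].append(read_pssm(directory / rel))
        return cls([FoldLibrary(fold_id, by_fold[fold_id]) for fold_id in order])


# ---------------------------------------------------------------------------
# Redundancy filters


def filter_near_identical(
    candidates: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    matrix: SubstitutionMatrix,
    threshold: float = 0.90,
) -> list[SequenceRecord]:
    """Drop candidates with global identity >= ``threshold`` to ANY reference.

    The threshold is inclusive. With an empty reference set the candidates
    are returned unchanged (with a warning).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not references:
        warnings.warn("filter_near_identical: empty reference set; nothing filtered")
        return list(candidates)
    kept = []
    for cand in candidates:
        if all(percent_identity(cand, ref, matrix) < threshold for ref in references):
            kept.append(cand)
    return kept


def filter_redundant(
    sequences: Sequence[SequenceRecord],
    matrix: SubstitutionMatrix,
    threshold: float = 0.40,
) -> list[SequenceRecord]:
    """Greedy keep-first redundancy sweep at the given identity threshold.

    In input order, a sequence is dropped when its global identity to any
    already-kept sequence is >= ``threshold`` (inclusive); output preserves
    input order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    kept: list[SequenceRecord] = []
    for seq in sequences:
        if all(percent_identity(seq, k, matrix) < threshold for k in kept):
            kept.append(seq)
    return kept


# ---------------------------------------------------------------------------
# PSSM construction


_COND_CACHE: dict[str, np.ndarray] = {}


def _conditional_substitution(matrix: SubstitutionMatrix) -> np.ndarray:
    """T[a, r] = P(r | a): BLOSUM-derived substitution probabilities, balanced
    (Sinkhorn) so that the background is exactly stationary."""
    cached = _COND_CACHE.get(matrix.name)
    if cached is not None:
        return cached
    p = ROBINSON_BACKGROUND
    joint = np.empty((20, 20))
    for i, a in enumerate(RESIDUE_ORDER):
        for j, b in enumerate(RESIDUE_ORDER):
            joint[i, j] = p[i] * p[j] * 2.0 ** (matrix.score(a, b) / 2.0)
    joint = 0.5 * (joint + joint.T)
    # symmetric Sinkhorn balancing to marginals p
    for _ in range(500):
        r = joint.sum(axis=1)
        if np.max(np.abs(r - p)) < 1e-13:
            break
        d = np.sqrt(p / r)
        joint = joint * d[:, None] * d[None, :]
    T = joint / joint.sum(axis=1, keepdims=True)
    _COND_CACHE[matrix.name] = T
    return T


def _henikoff_weights(rows: np.ndarray) -> np.ndarray:
    """Henikoff position-based sequence weights.

    ``rows`` is (N, L) of residue indices with -1 for gap/unknown. Weights
    sum to 1. Columns with no observed residue contribute nothing.
    """
    n_seq, n_col = rows.shape
    w = np.zeros(n_seq)
    for j in range(n_col):
        col = rows[:, j]
        observed = col[col >= 0]
        if observed.size == 0:
            continue
        types, counts = np.unique(observed, return_counts=True)
        r = len(types)
        count_of = dict(zip(types.tolist(), counts.tolist()))
        for k in range(n_seq):
            if col[k] >= 0:
                w[k] += 1.0 / (r * count_of[col[k]])
    total = w.sum()
    if total == 0:
        return np.full(n_seq, 1.0 / n_seq)
    return w / total


def _column_scores(
    f: np.ndarray, alpha: float, beta: float, T: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Half-bit log-odds scores for one column.

    ``f`` are the weighted observed frequencies, mixed with pseudocount
    target g = f @ T at weight ``beta`` against ``alpha`` effective
    observations. Because T leaves the background stationary, f = p gives
    scores of exactly zero.
    """
    g = f @ T
    q = (alpha * f + beta * g) / (alpha + beta)
    return 2.0 * np.log2(q / p)


def build_pssm(
    seed: SequenceRecord,
    homologs: Sequence[SequenceRecord],
    matrix: SubstitutionMatrix,
    pseudocount_weight: float = 10.0,
    fold_id: str = "",
    integer_scores: bool = False,
) -> PSSMRecord:
    """Build a position-specific scoring matrix from a seed and its homologs.

    Deterministic. Columns where the seed residue is 'X' score 0 everywhere.
    With ``integer_scores`` the half-bit scores are rounded to integers
    (PSI-BLAST style) instead of 2 decimals.
    """
    L = len(seed)
    if L == 0:
        raise ValueError("seed sequence is empty")
    # (N, L) residue-index rows on seed columns; -1 = gap or unknown
    rows = np.full((1 + len(homologs), L), -1, dtype=np.int64)
    rows[0] = [RESIDUE_INDEX.get(aa, -1) for aa in seed.residues]
    for k, hom in enumerate(homologs, start=1):
        aln = global_align(hom, seed, matrix)
        j = 0
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if cb != "-":
                if ca != "-":
                    rows[k, j] = RESIDUE_INDEX.get(ca, -1)
                j += 1
    weights = _henikoff_weights(rows)
    T = _conditional_substitution(matrix)
    p = ROBINSON_BACKGROUND
    beta = float(pseudocount_weight)
    scores = np.zeros((L, 20))
    for j in range(L):
        col = rows[:, j]
        mask = col >= 0
        if not mask.any():
            continue  # seed 'X' (and nothing else observed): neutral column
        f = np.zeros(20)
        np.add.at(f, col[mask], weights[mask])
        f = f / f.sum()
        alpha = float(len(np.unique(col[mask])) - 1)
        scores[j] = _column_scores(f, alpha, beta, T, p)
    decimals = 0 if integer_scores else 2
    scores = np.round(scores, decimals)
    return PSSMRecord(
        id=seed.id,
        fold_id=fold_id,
        reference=seed,
        scores=scores,
        pseudocount_weight=beta,
        source_count=1 + len(homologs),
    )


def build_fold_library(
    fold_id: str,
    seed_sets: Sequence[tuple[SequenceRecord, Sequence[SequenceRecord]]],
    matrix: SubstitutionMatrix,
    pseudocount_weight: float = 10.0,
    near_identical_threshold: float = 0.90,
    redundancy_threshold: float = 0.40,
) -> FoldLibrary:
    """Filter each homolog set and build one PSSM per seed.

    Homologs with >= ``near_identical_threshold`` identity to the seed are
    removed first, then the >= ``redundancy_threshold`` greedy redundancy
    sweep is applied; a set that collapses to empty still yields a PSSM
    (single-sequence limit).
    """
    if not seed_sets:
        raise ValueError("build_fold_library requires >= 1 seed set")
    pssms = []
    counts = {}
    for seed, homologs in seed_sets:
        non_identical = filter_near_identical(
            homologs, [seed], matrix, near_identical_threshold
        )
        non_redundant = filter_redundant(non_identical, matrix, redundancy_threshold)
        counts[seed.id] = {
            "homologs_in": len(homologs),
            "after_near_identical": len(non_identical),
            "after_redundancy": len(non_redundant),
        }
        pssms.append(
            build_pssm(
                seed,
                non_redundant,
                matrix,
                pseudocount_weight=pseudocount_weight,
                fold_id=fold_id,
            )
        )
    return FoldLibrary(fold_id, pssms, provenance={"filter_counts": counts})


def compile_collection(libraries: Sequence[FoldLibrary]) -> LibraryCollection:
    """Fix the profile axis order to the input library order."""
    return LibraryCollection(list(libraries))
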