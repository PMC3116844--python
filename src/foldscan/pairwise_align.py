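"""Alignment kernels: global sequence–sequence and local query-vs-PSSM.

The global aligner (Needleman–Wunsch, affine gaps) supplies the percent
identities used by the redundancy filters and the synthetic generator. The
local aligner (Smith–Waterman against a positional profile) is the native
replacement for an rps-BLAST search of a query against a library PSSM, with
Karlin–Altschul e-values attached analytically or by explicit Gumbel
calibration.

Gap convention: a gap of length k costs ``gap_open + k * gap_extend``, so a
single-residue gap under the default global settings (10, 0.5) costs 10.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from . import _dp
from .seq_formats import (
    RESIDUE_INDEX,
    RESIDUE_ORDER,
    PSSMRecord,
    SequenceRecord,
    SubstitutionMatrix,
)

#: Gapped Karlin–Altschul constants for BLOSUM62 with BLAST-default gap costs.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

#: Published ungapped lambda for integer BLOSUM62 scores (nats per half-bit).
UNGAPPED_BLOSUM62_LAMBDA = 0.3176


def encode(residues: str) -> np.ndarray:
    """Map residues to indices into RESIDUE_ORDER; 'X' maps to 20."""
    return np.array([RESIDUE_INDEX.get(aa, 20) for aa in residues], dtype=np.int64)


def _matrix_profile(subject: str, matrix: SubstitutionMatrix) -> np.ndarray:
    """Profile matrix for sequence-vs-sequence alignment: one row per subject residue."""
    prof = np.empty((len(subject), 21))
    for j, aa in enumerate(subject):
        for r, other in enumerate(RESIDUE_ORDER):
            prof[j, r] = matrix.score(other, aa)
        prof[j, 20] = matrix.score("X", aa)
    return prof


def pssm_profile(pssm: PSSMRecord, x_score: float = -1.0) -> np.ndarray:
    """Profile matrix for query-vs-PSSM alignment; query 'X' scores ``x_score``."""
    prof = np.empty((len(pssm), 21))
    prof[:, :20] = pssm.scores
    prof[:, 20] = x_score
    return prof


@dataclass(frozen=True)
class GlobalAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


@dataclass(frozen=True)
class ProfileAlignment:
    """A local alignment between a query and one library PSSM.

    Coordinates are 1-based inclusive; ``pairs`` lists the aligned
    (query position, PSSM position) matches, strictly increasing in both.
    """

    query_id: str
    pssm_id: str
    fold_id: str
    qstart: int
    qend: int
    pstart: int
    pend: int
    pairs: tuple[tuple[int, int], ...]
    score: float
    evalue: float
    coverage: float


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Extreme-value statistics of local alignment scores: E = K·m·n·exp(−λS)."""

    lam: float = DEFAULT_LAMBDA
    K: float = DEFAULT_K
    m: int = 100
    n_db: int = 10_000

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: SubstitutionMatrix,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> GlobalAlignment:
    """Optimal Needleman–Wunsch global alignment with affine gap costs.

    Identity is the fraction of alignment columns (gap columns included)
    where the two residues are identical.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("global_align requires non-empty sequences")
    q = encode(a.residues)
    prof = _matrix_profile(b.residues, matrix)
    M, Ix, Iy, pM, pX, pY = _dp.global_affine(q, prof, float(gap_open), float(gap_extend))
    n, m = len(a), len(b)
    score = M[n, m]
    state = 0
    if Ix[n, m] > score:
        score, state = Ix[n, m], 1
    if Iy[n, m] > score:
        score, state = Iy[n, m], 2
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a.residues[i - 1])
            out_b.append(b.residues[j - 1])
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            out_a.append(a.residues[i - 1])
            out_b.append("-")
            state = pX[i, j]
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b.residues[j - 1])
            state = pY[i, j]
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    ident = sum(x == y for x, y in zip(aligned_a, aligned_b)) / len(aligned_a)
    return GlobalAlignment(aligned_a, aligned_b, float(score), ident)


def percent_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: SubstitutionMatrix,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Identity fraction of the optimal global alignment, in [0, 1]."""
    return global_align(a, b, matrix, gap_open, gap_extend).identity


def local_profile_align(
    query: SequenceRecord,
    pssm: PSSMRecord,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    ka_params: KarlinAltschulParams | None = None,
) -> ProfileAlignment | None:
    """Best Smith–Waterman local alignment of ``query`` against one PSSM.

    Returns ``None`` when no cell scores above zero. Only the single best
    alignment is reported (no sub-optimal HSPs). Co-optimal tracebacks are
    resolved deterministically: earliest end cell in (query, PSSM) order,
    diagonal moves preferred.
    """
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be non-negative")
    q = encode(query.residues)
    prof = pssm_profile(pssm)
    M, Ix, Iy, pM, pX, pY, best, bi, bj = _dp.local_affine(
        q, prof, float(gap_open), float(gap_extend)
    )
    if best <= 0.0:
        return None
    pairs: list[tuple[int, int]] = []
    i, j, state = bi, bj, 0
    while True:
        if state == 0:
            pairs.append((i, j))
            prev = pM[i, j]
            i -= 1
            j -= 1
            if prev == 3:
                break
            state = prev
        elif state == 1:
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
    pairs.reverse()
    qstart, pstart = pairs[0]
    qend, pend = pairs[-1]
    coverage = (pend - pstart + 1) / len(pssm)
    params = ka_params if ka_params is not None else KarlinAltschulParams(
        m=len(query), n_db=len(pssm)
    )
    return ProfileAlignment(
        query_id=query.id,
        pssm_id=pssm.id,
        fold_id=pssm.fold_id,
        qstart=qstart,
        qend=qend,
        pstart=pstart,
        pend=pend,
        pairs=tuple(pairs),
        score=float(best),
        evalue=estimate_evalue(float(best), params),
        coverage=coverage,
    )


def estimate_evalue(score: float, params: KarlinAltschulParams) -> float:
    """Karlin–Altschul expect value E = K · m · n_db · exp(−λ · S)."""
    if not math.isfinite(score):
        raise ValueError("non-finite alignment score")
    return params.K * params.m * params.n_db * math.exp(-params.lam * score)


def calibrate_params(
    pssm: PSSMRecord,
    background: np.ndarray,
    n_shuffles: int = 500,
    seed: int = 0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_length: int | None = None,
) -> KarlinAltschulParams:
    """Fit λ and K by maximum-likelihood Gumbel fit to null alignment scores.

    Random queries are drawn i.i.d. from ``background`` (length-20 frequency
    vector over RESIDUE_ORDER) and locally aligned to the PSSM; the resulting
    score sample is fit with a right-skewed Gumbel, giving λ = 1/scale and
    K = exp(loc/scale) / (m·n). Deterministic given ``seed``.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 for a stable fit")
    if np.all(pssm.scores.max(axis=1) <= 0):
        raise ValueError(
            f"PSSM {pssm.id!r} is degenerate (no column scores above zero); "
            "cannot calibrate"
        )
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    m = query_length if query_length is not None else len(pssm)
    rng = np.random.default_rng(seed)
    prof = pssm_profile(pssm)
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        q = rng.choice(20, size=m, p=background).astype(np.int64)
        *_, best, _, _ = _dp.local_affine(q, prof, float(gap_open), float(gap_extend))
        scores[k] = best
    loc, scale = scipy.stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    K = math.exp(loc / scale) / (m * len(pssm))
    return KarlinAltschulParams(lam=lam, K=K, m=m, n_db=len(pssm))
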