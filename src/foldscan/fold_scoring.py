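"""The core of the method: fold-specific scores, structural sequence
profiles, and the structural similarity score.

A query is scanned against every PSSM of a fold library; alignments failing
the e-value / coverage thresholds are discarded. Each query residue that is
identically or conservatively aligned (substitution-matrix score > 0) to a
PSSM reference residue accumulates that BLOSUM score into its positional
score P_i. The fold-specific score is sum_i max(P_i, 0) / n for query length
n. Across an ordered collection of fold libraries, the vector of
fold-specific scores is the query's *structural sequence profile*, and the
*structural similarity score* of two proteins is the Pearson correlation of
their profiles. Pairs above 0.1 are conventionally called structurally
related.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fold_library import FoldLibrary, LibraryCollection
from .pairwise_align import (
    KarlinAltschulParams,
    ProfileAlignment,
    local_profile_align,
)
from .seq_formats import SequenceRecord, SubstitutionMatrix

#: Structural similarity scores above this are conventionally called related.
DEFAULT_SIMILARITY_THRESHOLD = 0.1


@dataclass(frozen=True)
class ScanThresholds:
    """Alignment acceptance filters: keep E <= max_evalue AND coverage >= min_coverage."""

    max_evalue: float
    min_coverage: float

    def __post_init__(self):
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if not 0 <= self.min_coverage <= 1:
            raise ValueError("min_coverage must be in [0, 1]")

    @classmethod
    def strict(cls) -> "ScanThresholds":
        """Statistically significant alignments only: e-value 0.01, no coverage filter."""
        return cls(0.01, 0.0)

    @classmethod
    def permissive(cls) -> "ScanThresholds":
        """Any e-value (1e10) but >= 80% PSSM coverage."""
        return cls(1e10, 0.80)

    def accepts(self, alignment: ProfileAlignment) -> bool:
        return (
            alignment.evalue <= self.max_evalue
            and alignment.coverage >= self.min_coverage
        )


PRESETS = {"strict": ScanThresholds.strict, "permissive": ScanThresholds.permissive}


@dataclass(frozen=True)
class PositionalScoreTrack:
    """Per-residue accumulated conservation scores P_i for one query, one fold."""

    query_id: str
    fold_id: str
    scores: np.ndarray  # length n, all >= 0

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class StructuralSequenceProfile:
    """A query's vector of fold-specific scores, one entry per fold library."""

    query_id: str
    fold_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.fold_ids),):
            raise ValueError("profile length must equal the number of fold axes")
        if np.any(values < 0):
            raise ValueError("fold-specific scores are non-negative")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        return float(self.values.std())


def scan(
    query: SequenceRecord,
    library: FoldLibrary,
    thresholds: ScanThresholds | None = None,
    ka_params: KarlinAltschulParams | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[ProfileAlignment]:
    """Align ``query`` to every PSSM in ``library``; keep threshold-passing hits.

    E-values use a shared search-space size: m = query length, n_db = total
    PSSM columns in the library (unless explicit ``ka_params`` are given).
    """
    thresholds = thresholds or ScanThresholds.strict()
    params = ka_params or KarlinAltschulParams(
        m=len(query), n_db=max(library.total_columns, 1)
    )
    hits = []
    for pssm in library.pssms:
        aln = local_profile_align(
            query, pssm, gap_open=gap_open, gap_extend=gap_extend, ka_params=params
        )
        if aln is not None and thresholds.accepts(aln):
            hits.append(aln)
    return hits


def positional_scores(
    query: SequenceRecord,
    alignments: list[ProfileAlignment],
    matrix: SubstitutionMatrix,
    reference_lookup: dict[str, str] | None = None,
) -> PositionalScoreTrack:
    """Accumulate BLOSUM scores of identically/conservatively aligned residues.

    For every aligned pair the query residue is scored against the PSSM's
    reference residue; pairs that are neither identical nor positively
    scoring contribute nothing, as do gaps and pairs involving 'X'.
    ``reference_lookup`` maps pssm_id -> reference residues; required when
    alignments are scored (it is supplied by :func:`structural_profile`).
    """
    n = len(query)
    P = np.zeros(n)
    fold_id = alignments[0].fold_id if alignments else ""
    for aln in alignments:
        if aln.query_id != query.id:
            raise ValueError(
                f"alignment for {aln.query_id!r} scored against query {query.id!r}"
            )
        if aln.fold_id != fold_id:
            raise ValueError("alignments span multiple fold libraries")
        if reference_lookup is None or aln.pssm_id not in reference_lookup:
            raise ValueError(f"no reference sequence for PSSM {aln.pssm_id!r}")
        reference = reference_lookup[aln.pssm_id]
        for qi, pj in aln.pairs:
            if not (1 <= qi <= n and 1 <= pj <= len(reference)):
                raise ValueError(
                    f"alignment pair ({qi}, {pj}) out of range for "
                    f"query {query.id!r} / PSSM {aln.pssm_id!r}"
                )
            q = query.residues[qi - 1]
            r = reference[pj - 1]
            if q == "X" or r == "X":
                continue
            s = matrix.score(q, r)
            if q == r or s > 0:
                P[qi - 1] += s
    return PositionalScoreTrack(query_id=query.id, fold_id=fold_id, scores=P)


def fold_specific_score(track: PositionalScoreTrack) -> float:
    """Sum of positive positional scores divided by the query length."""
    P = track.scores
    n = len(P)
    if n == 0:
        return 0.0
    return float(np.maximum(P, 0.0).sum() / n)


def structural_profile(
    query: SequenceRecord,
    collection: LibraryCollection,
    matrix: SubstitutionMatrix,
    thresholds: ScanThresholds | None = None,
    ka_params: KarlinAltschulParams | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> StructuralSequenceProfile:
    """Fold-specific score against every library, in collection axis order."""
    thresholds = thresholds or ScanThresholds.strict()
    values = []
    for library in collection:
        hits = scan(
            query, library, thresholds, ka_params, gap_open=gap_open, gap_extend=gap_extend
        )
        lookup = {p.id: p.reference.residues for p in library.pssms}
        track = positional_scores(query, hits, matrix, reference_lookup=lookup)
        values.append(fold_specific_score(track))
    return StructuralSequenceProfile(
        query_id=query.id, fold_ids=collection.fold_ids, values=np.array(values)
    )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with the zero-variance convention: return 0.0.

    An undefined correlation (either vector constant) is read as "no
    evidence of similarity", keeping all-against-all tables NaN-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def structural_similarity(
    x: StructuralSequenceProfile, y: StructuralSequenceProfile
) -> float:
    """Pearson correlation of two structural sequence profiles, in [-1, 1]."""
    if x.fold_ids != y.fold_ids:
        raise ValueError("profiles have mismatched fold axes")
    if len(x.fold_ids) < 2:
        raise ValueError("structural similarity requires >= 2 fold axes")
    return pearson(x.values, y.values)


def predict_fold(profile: StructuralSequenceProfile) -> str:
    """Fold with the highest fold-specific score; "unassigned" for an all-zero
    profile; ties resolve to the earliest axis."""
    if np.all(profile.values == 0.0):
        return "unassigned"
    return profile.fold_ids[int(np.argmax(profile.values))]


def similarity_matrix(
    profiles: list[StructuralSequenceProfile],
    truth: dict[str, str] | None = None,
):
    """All-against-all structural similarity, as an evaluation-ready table.

    ``truth`` maps query id -> fold id; when given, same-fold pairs are
    labeled positive.
    """
    from .evaluation import RankedPairTable  # local import to avoid a cycle

    if len(profiles) < 2:
        raise ValueError("similarity_matrix requires >= 2 profiles")
    axes = profiles[0].fold_ids
    for p in profiles[1:]:
        if p.fold_ids != axes:
            raise ValueError("profiles have mismatched fold axes")
    ids = tuple(p.query_id for p in profiles)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate query ids")
    n = len(profiles)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = structural_similarity(profiles[i], profiles[j])
            scores[i, j] = scores[j, i] = s
    labels = None
    if truth is not None:
        labels = {
            frozenset((a, b)): truth[a] == truth[b]
            for i, a in enumerate(ids)
            for b in ids[i + 1:]
        }
    return RankedPairTable(ids=ids, scores=scores, labels=labels)
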