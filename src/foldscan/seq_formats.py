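"""Readers and writers for sequences, substitution matrices, PSSMs and library manifests.

All downstream modules consume only the types defined here. Sequence
coordinates in every serialized file are 1-based and inclusive; in memory,
Python 0-based indexing is used throughout the package (this module is the
single place where that convention is documented).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: Canonical residue order used in PSSM files and everywhere a 20-vector appears.
RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"
RESIDUE_INDEX = {aa: i for i, aa in enumerate(RESIDUE_ORDER)}

_VALID_RESIDUES = frozenset(RESIDUE_ORDER + "X")


class FormatError(ValueError):
    """Raised on malformed sequence, matrix, PSSM or manifest input."""


@dataclass(frozen=True)
class SequenceRecord:
    """An amino-acid sequence over the 20-letter alphabet plus 'X' (unknown)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record requires a non-empty id")
        res = self.residues.upper()
        if len(res) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(res) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid residues {sorted(bad)!r}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue substitution matrix (BLOSUM62 by default)."""

    name: str
    _scores: dict = field(repr=False)

    def score(self, a: str, b: str) -> float:
        """Score for the ordered residue pair (a, b); 'X' rows default to -1."""
        try:
            return self._scores[a, b]
        except KeyError:
            if a == "X" or b == "X":
                return -1.0
            raise KeyError(f"no score for residue pair ({a!r}, {b!r})")

    def __call__(self, a: str, b: str) -> float:
        return self.score(a, b)

    def row(self, a: str) -> np.ndarray:
        """Scores of residue ``a`` against :data:`RESIDUE_ORDER`, as a vector."""
        return np.array([self.score(a, b) for b in RESIDUE_ORDER])


def load_substitution_matrix(name_or_path: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a built-in NCBI matrix by name, or an NCBI-format matrix file by path.

    The built-in "BLOSUM62" is Biopython's copy of the NCBI distribution.
    Asymmetric files are rejected.
    """
    path = Path(name_or_path)
    if path.exists() and path.is_file():
        mat = substitution_matrices.read(str(path))
        name = path.stem
    else:
        try:
            mat = substitution_matrices.load(name_or_path.upper())
        except FileNotFoundError:
            raise FormatError(f"unknown substitution matrix {name_or_path!r}")
        name = name_or_path.upper()
    scores: dict = {}
    alphabet = [a for a in mat.alphabet if a != "*"]
    for a in alphabet:
        for b in alphabet:
            scores[a, b] = float(mat[a, b])
    for a in alphabet:
        for b in alphabet:
            if scores[a, b] != scores[b, a]:
                raise FormatError(
                    f"matrix {name!r} is asymmetric at ({a}, {b})"
                )
    for aa in RESIDUE_ORDER:
        if (aa, aa) not in scores:
            raise FormatError(f"matrix {name!r} missing standard residue {aa!r}")
    return SubstitutionMatrix(name=name, _scores=scores)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Parse a FASTA file into validated :class:`SequenceRecord` objects.

    Sequences are uppercased and trailing '*' terminators stripped. An empty
    file, a sequence-free header, or text before the first header is a
    :class:`FormatError` naming the offending record or line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    first = next(line for line in text.splitlines() if line.strip())
    if not first.startswith(">"):
        raise FormatError(f"{path}: line 1: expected '>' header, got {first[:30]!r}")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records as standard FASTA with 60-column sequence wrapping."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# PSSM text format
#
#   # pssm_id: <id>
#   # fold_id: <fold>
#   # pseudocount_weight: <beta>
#   # source_count: <int>
#   # residue_order: ARNDCQEGHILKMFPSTWYV
#   <pos> <ref_residue> <20 scores, 2-decimal fixed point>
#
# Positions are 1-based. Round-trips bit-exactly because scores are stored
# (and held in memory) at 2-decimal precision.


@dataclass(frozen=True)
class PSSMRecord:
    """Serialized form of a fold-library PSSM.

    ``scores[j, r]`` is the log-odds score of residue ``RESIDUE_ORDER[r]`` at
    position ``j`` (0-based internally), in half-bit units.
    """

    id: str
    fold_id: str
    reference: SequenceRecord
    scores: np.ndarray  # (L, 20) float
    pseudocount_weight: float = 10.0
    source_count: int = 1

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.reference), 20):
            raise FormatError(
                f"PSSM {self.id!r}: score shape {scores.shape} does not match "
                f"reference length {len(self.reference)}"
            )
        if not np.all(np.isfinite(scores)):
            raise FormatError(f"PSSM {self.id!r}: non-finite scores")
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.reference)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PSSMRecord)
            and self.id == other.id
            and self.fold_id == other.fold_id
            and self.reference == other.reference
            and np.array_equal(self.scores, other.scores)
            and self.pseudocount_weight == other.pseudocount_weight
            and self.source_count == other.source_count
        )


def write_pssm(pssm: PSSMRecord, path: str | os.PathLike) -> None:
    lines = [
        f"# pssm_id: {pssm.id}",
        f"# fold_id: {pssm.fold_id}",
        f"# length: {len(pssm.reference)}",
        f"# pseudocount_weight: {pssm.pseudocount_weight:g}",
        f"# source_count: {pssm.source_count}",
        f"# residue_order: {RESIDUE_ORDER}",
    ]
    for j, aa in enumerate(pssm.reference.residues):
        row = " ".join(f"{s:.2f}" for s in pssm.scores[j])
        lines.append(f"{j + 1} {aa} {row}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pssm(path: str | os.PathLike) -> PSSMRecord:
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[str, list[float]]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            header[key.strip()] = value.strip()
            continue
        fields = line.split()
        if len(fields) != 22:
            raise FormatError(f"{path}:{lineno}: expected 22 fields, got {len(fields)}")
        rows.append((fields[1], [float(x) for x in fields[2:]]))
    for required in ("pssm_id", "fold_id", "residue_order"):
        if required not in header:
            raise FormatError(f"{path}: missing header line {required!r}")
    if header["residue_order"] != RESIDUE_ORDER:
        raise FormatError(f"{path}: unexpected residue order {header['residue_order']!r}")
    if "length" in header and int(header["length"]) != len(rows):
        raise FormatError(
            f"{path}: {len(rows)} score rows but declared length {header['length']}"
        )
    reference = SequenceRecord(
        id=header["pssm_id"], residues="".join(aa for aa, _ in rows)
    )
    scores = np.array([s for _, s in rows], dtype=float)
    # shape check against the declared reference happens in PSSMRecord
    return PSSMRecord(
        id=header["pssm_id"],
        fold_id=header["fold_id"],
        reference=reference,
        scores=scores,
        pseudocount_weight=float(header.get("pseudocount_weight", 10.0)),
        source_count=int(header.get("source_count", 1)),
    )


# ---------------------------------------------------------------------------
# Collection manifest
#
# Plain-text, one line per PSSM:  <fold_id>\t<relative path>
# Fold order of first appearance defines the profile vector axes.


def write_collection_manifest(
    entries: Sequence[tuple[str, str]], path: str | os.PathLike
) -> None:
    """Write (fold_id, relative PSSM path) rows; row order defines axis order."""
    lines = [f"{fold_id}\t{rel}" for fold_id, rel in entries]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_collection_manifest(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read manifest rows; verify fold ids are contiguous and member files exist."""
    path = Path(path)
    entries: list[tuple[str, str]] = []
    seen_folds: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'fold<TAB>path'")
        fold_id, rel = parts
        if fold_id in seen_folds and seen_folds[-1] != fold_id:
            raise FormatError(f"{path}:{lineno}: duplicate fold id {fold_id!r}")
        if fold_id not in seen_folds:
            seen_folds.append(fold_id)
        member = path.parent / rel
        if not member.exists():
            raise FormatError(f"{path}:{lineno}: missing PSSM file {rel!r}")
        entries.append((fold_id, rel))
    return entries
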