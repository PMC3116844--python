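"""Self-contained benchmark worlds: fold families with controlled
twilight-zone divergence, plus labeled held-out queries.

Each synthetic fold is an ancestor sequence drawn from the Robinson–
Robinson background; seeds, homologs and queries are independent mutants
of that ancestor whose global (Needleman–Wunsch, BLOSUM62, 10/0.5) percent
identity to the ancestor is driven into a target band (default 0.20–0.30,
the twilight-zone regime).

Two features of real fold families are emulated so that the
positively-scoring substitution structure survives at low identity —
without it, the twilight zone carries no fold signal at all:

* site-rate heterogeneity: each fold carries a conservation mask of
  alternating blocks (structural-core blocks mutate ~20x slower than
  loop-like blocks), shared by every member of the fold, so divergence
  concentrates in the variable regions;
* conservative exchange: substitutions are proposed from BLOSUM-derived
  conditional exchange probabilities, so replacements tend to be
  positively scoring.

The mutation model is a biased substitution/indel process, not an explicit
phylogeny: the method under test is alignment-based and the identity band
is the controlled variable.

All randomness flows from one integer seed through a single named
generator stream; two runs with the same spec are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fold_library import (
    ROBINSON_BACKGROUND,
    FoldLibrary,
    LibraryCollection,
    _conditional_substitution,
    build_fold_library,
    compile_collection,
)
from .pairwise_align import percent_identity
from .seq_formats import (
    RESIDUE_ORDER,
    SequenceRecord,
    SubstitutionMatrix,
    write_fasta,
)


@dataclass(frozen=True)
class SyntheticFoldSpec:
    """Study conditions for one benchmark world.

    Defaults mirror the twilight-zone benchmark regime: sequence lengths of
    135 +/- 90 (clamped at 40 so the identity band is resolvable at ~1/n
    granularity), a 0.20-0.30 pairwise-identity band to the fold ancestor,
    and a light indel process.
    """

    n_folds: int = 8
    seeds_per_fold: int = 2
    homologs_per_seed: int = 15
    queries_per_fold: int = 5
    length_mean: float = 135.0
    length_sd: float = 90.0
    min_length: int = 40
    identity_band: tuple[float, float] = (0.20, 0.30)
    indel_rate: float = 0.02
    conserved_block_len: float = 8.0
    variable_block_len: float = 12.0
    conserved_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.identity_band
        if not (0 < lo < hi < 1):
            raise ValueError("identity band must satisfy 0 < lo < hi < 1")
        for name in ("n_folds", "seeds_per_fold", "homologs_per_seed", "queries_per_fold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SyntheticBenchmark:
    """A generated world: per-fold sequence sets plus a labeled query set."""

    spec: SyntheticFoldSpec
    fold_ids: list[str]
    seed_sets: dict[str, list[tuple[SequenceRecord, list[SequenceRecord]]]]
    queries: list[SequenceRecord]
    truth: dict[str, str]  # query id -> fold id

    def __post_init__(self):
        for qid, fold in self.truth.items():
            if fold not in self.fold_ids:
                raise ValueError(f"truth label {fold!r} for {qid!r} is not a fold")
        missing = {q.id for q in self.queries} - set(self.truth)
        if missing:
            raise ValueError(f"unlabeled queries: {sorted(missing)}")

    def write(self, out_dir: str | Path) -> None:
        """Write FASTA trees, the truth TSV, and a ready-to-build library layout."""
        out = Path(out_dir)
        for fold_id in self.fold_ids:
            fold_dir = out / fold_id
            hom_dir = fold_dir / "homologs"
            hom_dir.mkdir(parents=True, exist_ok=True)
            seeds = [seed for seed, _ in self.seed_sets[fold_id]]
            write_fasta(seeds, fold_dir / "seeds.fasta")
            for seed, homologs in self.seed_sets[fold_id]:
                write_fasta(homologs, hom_dir / f"{seed.id}.fasta")
        write_fasta(self.queries, out / "queries.fasta")
        lines = [f"{q.id}\t{self.truth[q.id]}" for q in self.queries]
        (out / "truth.tsv").write_text("\n".join(lines) + "\n")

    def build_collection(
        self, matrix: SubstitutionMatrix, pseudocount_weight: float = 10.0
    ) -> LibraryCollection:
        """Build and compile one fold library per fold, in fold-id order."""
        libraries = [
            build_fold_library(
                fold_id,
                self.seed_sets[fold_id],
                matrix,
                pseudocount_weight=pseudocount_weight,
            )
            for fold_id in self.fold_ids
        ]
        return compile_collection(libraries)


def generate_ancestor(
    length: int,
    rng: np.random.Generator,
    background: np.ndarray | None = None,
    seq_id: str = "ancestor",
) -> SequenceRecord:
    """Draw an i.i.d. sequence of ``length`` residues from ``background``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    p = ROBINSON_BACKGROUND if background is None else np.asarray(background, float)
    p = p / p.sum()
    idx = rng.choice(20, size=length, p=p)
    return SequenceRecord(id=seq_id, residues="".join(RESIDUE_ORDER[i] for i in idx))


def conservation_mask(
    length: int,
    rng: np.random.Generator,
    conserved_block_len: float = 8.0,
    variable_block_len: float = 12.0,
) -> np.ndarray:
    """Alternating conserved/variable blocks with geometric lengths.

    Emulates contiguous structural cores (helices/strands) separated by
    loop-like variable regions; whether the sequence starts conserved is
    random. Returns a boolean array, True = conserved site.
    """
    mask = np.empty(length, dtype=bool)
    conserved = bool(rng.random() < 0.5)
    i = 0
    while i < length:
        mean = conserved_block_len if conserved else variable_block_len
        block = int(rng.geometric(1.0 / mean))
        mask[i : i + block] = conserved
        i += block
        conserved = not conserved
    return mask


def mutate_to_identity(
    ancestor: SequenceRecord,
    target_identity: float,
    indel_rate: float,
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
    seq_id: str | None = None,
    site_rates: np.ndarray | None = None,
    band_halfwidth: float = 0.03,
    max_rounds: int = 400,
) -> SequenceRecord:
    """Mutate a copy of ``ancestor`` until its global identity to the
    ancestor lies in ``target_identity`` +/- ``band_halfwidth``.

    Indels are applied first (count ~ Binomial(n, indel_rate), geometric
    lengths, insertions from the background), then substitutions proposed
    from the BLOSUM-conditional exchange distribution are applied in
    batches, re-measuring the Needleman–Wunsch identity after each batch.
    ``site_rates`` (per-ancestor-position relative mutation rates) bias
    both indel placement and substitution sites; slow sites model the
    conserved structural core of the fold. Raises RuntimeError when the
    band is not reached within ``max_rounds`` measurement rounds (e.g. an
    unreachably high target with indels on).
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    seq_id = seq_id or f"{ancestor.id}_mut"
    if target_identity >= 1.0 - 1e-12:
        return SequenceRecord(id=seq_id, residues=ancestor.residues)
    lo = target_identity - band_halfwidth
    hi = target_identity + band_halfwidth
    T = _conditional_substitution(matrix)
    residues = list(ancestor.residues)
    if site_rates is None:
        rates = [1.0] * len(residues)
    else:
        if len(site_rates) != len(residues):
            raise ValueError("site_rates length must match the ancestor length")
        rates = [float(r) for r in site_rates]
    origin = list(range(len(residues)))  # ancestor index per position, -1 = inserted

    # exchange CDFs per source residue (diagonal zeroed): cheap inverse-CDF draws
    Tz = T.copy()
    np.fill_diagonal(Tz, 0.0)
    Tz = Tz / Tz.sum(axis=1, keepdims=True)
    Tcdf = np.cumsum(Tz, axis=1)

    def draw_position(cdf: np.ndarray) -> int:
        return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))

    n_indels = rng.binomial(len(residues), indel_rate)
    for _ in range(n_indels):
        pos = draw_position(np.cumsum(rates))
        size = max(int(rng.geometric(0.5)), 1)
        if rng.random() < 0.5 and len(residues) > size + 10:
            del residues[pos : pos + size]
            del rates[pos : pos + size]
            del origin[pos : pos + size]
        else:
            insert = generate_ancestor(size, rng).residues
            residues[pos:pos] = list(insert)
            rates[pos:pos] = [1.0] * size  # inserted material is variable
            origin[pos:pos] = [-1] * size

    rate_cdf = np.cumsum(rates)

    def substitute_one() -> None:
        pos = draw_position(rate_cdf)
        a = RESIDUE_ORDER.find(residues[pos])
        if a >= 0:
            residues[pos] = RESIDUE_ORDER[
                int(np.searchsorted(Tcdf[a], rng.random(), side="right"))
            ]

    def hamming() -> float:
        same = sum(
            1
            for pos, orig in enumerate(origin)
            if orig >= 0 and residues[pos] == ancestor.residues[orig]
        )
        return same / len(ancestor)

    def measure() -> float:
        return percent_identity(
            SequenceRecord(id="m", residues="".join(residues)), ancestor, matrix
        )

    # coarse phase: drive the cheap positional (Hamming) identity just above
    # the band before paying for Needleman-Wunsch measurements
    proxy_target = hi + 0.05
    guard = 50 * len(residues)
    while hamming() > proxy_target and guard > 0:
        for _ in range(max(1, int((hamming() - proxy_target) * len(residues) * 0.5))):
            substitute_one()
            guard -= 1

    identity = measure()
    for _ in range(max_rounds):
        if lo <= identity <= hi:
            return SequenceRecord(id=seq_id, residues="".join(residues))
        if identity < lo:
            break  # overshot; substitutions cannot raise identity
        # a substitution lowers identity by at most ~1/n; take a half-step
        batch = max(1, int((identity - hi) * len(residues) * 0.5))
        if identity - hi < 2.0 / len(residues):
            batch = 1
        for _ in range(batch):
            substitute_one()
        identity = measure()
    raise RuntimeError(
        f"could not reach identity {target_identity:.2f} +/- {band_halfwidth:.2f} "
        f"for {seq_id!r} (last measured {identity:.3f})"
    )


def make_benchmark(spec: SyntheticFoldSpec) -> SyntheticBenchmark:
    """Generate a complete labeled benchmark world from one integer seed."""
    rng = np.random.default_rng(spec.seed)
    from .seq_formats import load_substitution_matrix

    matrix = load_substitution_matrix("BLOSUM62")
    lo, hi = spec.identity_band
    fold_ids = [f"fold{k:02d}" for k in range(1, spec.n_folds + 1)]
    seed_sets: dict[str, list[tuple[SequenceRecord, list[SequenceRecord]]]] = {}
    queries: list[SequenceRecord] = []
    truth: dict[str, str] = {}

    def mutant(
        ancestor: SequenceRecord, seq_id: str, site_rates: np.ndarray
    ) -> SequenceRecord:
        target = rng.uniform(lo, hi)
        for attempt in range(5):
            try:
                return mutate_to_identity(
                    ancestor, target, spec.indel_rate, matrix, rng,
                    seq_id=seq_id, site_rates=site_rates,
                )
            except RuntimeError:
                if attempt == 4:
                    raise
        raise AssertionError("unreachable")

    for fold_id in fold_ids:
        length = max(spec.min_length, int(round(rng.normal(spec.length_mean, spec.length_sd))))
        ancestor = generate_ancestor(length, rng, seq_id=f"{fold_id}_anc")
        mask = conservation_mask(
            length, rng, spec.conserved_block_len, spec.variable_block_len
        )
        site_rates = np.where(mask, spec.conserved_rate, 1.0)
        sets = []
        for s in range(1, spec.seeds_per_fold + 1):
            seed = mutant(ancestor, f"{fold_id}_s{s}", site_rates)
            homologs = [
                mutant(ancestor, f"{fold_id}_s{s}_h{h:02d}", site_rates)
                for h in range(1, spec.homologs_per_seed + 1)
            ]
            sets.append((seed, homologs))
        seed_sets[fold_id] = sets
        for qn in range(1, spec.queries_per_fold + 1):
            q = mutant(ancestor, f"{fold_id}_q{qn}", site_rates)
            queries.append(q)
            truth[q.id] = fold_id
    return SyntheticBenchmark(
        spec=spec, fold_ids=fold_ids, seed_sets=seed_sets, queries=queries, truth=truth
    )
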