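# Methods

This note documents the models, numerical choices and limitations behind
`foldscan`. It is the design record; empirical claims here are limited to
what the test suite and `scripts/acceptance.py` themselves compute.

## Alignment kernels

Two affine-gap dynamic-programming kernels (numba-jitted) underlie
everything. A gap of length *k* costs `gap_open + k·gap_extend` (the EMBOSS
convention), so a single-residue gap under the global defaults (10, 0.5)
costs 10.5. Gap-state switches (a deletion run directly followed by an
insertion run) are allowed and open a fresh gap, making the kernels exact
over the space of all gapped alignments — the property the brute-force
oracle tests assert.

* **Global (Needleman–Wunsch)** — sequence vs sequence, BLOSUM62,
  gap 10/0.5 by default. Supplies the percent identities used by the
  redundancy filters and the synthetic generator. Identity is the fraction
  of alignment columns (gap columns included) with identical residues.
* **Local (Smith–Waterman)** — query vs positional profile, gap 11/1 by
  default (the BLAST default regime for BLOSUM62-scaled scores). Only the
  single best alignment per (query, PSSM) is returned; sub-optimal HSPs are
  not collected. Alignments start and end on an aligned pair (edge gaps
  cannot improve an optimum under positive gap costs). Co-optimal
  tracebacks resolve deterministically: earliest end cell in row-major
  (query, PSSM) order, diagonal moves preferred.

A query 'X' residue scores −1 against every PSSM column; in
sequence–sequence mode 'X' uses the matrix's own X row.

## E-value statistics

Local alignment scores follow Karlin–Altschul extreme-value statistics:
`E = K·m·n_db·exp(−λS)` with query length *m* and total library columns
*n_db*. Defaults are the gapped BLOSUM62 constants λ = 0.267 nats per
score unit, K = 0.041; `calibrate_params` refits both by a
maximum-likelihood Gumbel fit to the scores of background-composition
random queries (λ = 1/scale, K = exp(loc/scale)/(m·n)), deterministic
given its seed. Effective-length corrections are not reproduced; *m* and
*n_db* are explicit parameters.

## PSSM construction

Each library PSSM is built from one seed sequence plus pre-collected
homologs (homolog acquisition — e.g. an iterative database expansion — is
an input step, not part of the computation). Homologs are placed on seed
columns by global alignment to the seed. Observed column frequencies are
weighted with Henikoff position-based sequence weights and mixed with
substitution-matrix pseudocounts:

    q_j = (α_j f_j + β g_j) / (α_j + β),   g_j = f_j T

where α_j is the number of distinct residue types at column j minus one,
β = 10 is the single pseudocount weight, and T holds BLOSUM62-derived
conditional substitution probabilities, Sinkhorn-balanced so the
Robinson–Robinson background is exactly stationary. Scores are
`2·log2(q_j(r)/p(r))` — half-bit units, the same scale as integer BLOSUM62
(the PSI-BLAST convention), which keeps the BLAST-default gap penalties and
Karlin–Altschul constants on their native scale — rounded to 2 decimals
(integers available via a flag). Consequences used as test oracles: with
no homologs a column reduces to (approximately) the BLOSUM62 row of the
seed residue; a column observed at background frequencies scores zero;
seed 'X' columns are neutral (all-zero).

The 90%/40% redundancy filters are inclusive at the threshold and the
40% sweep is greedy keep-first in input order, so output order and content
are deterministic.

## Fold scoring and profiles

Positional scores accumulate the BLOSUM62 score of every identically or
conservatively aligned pair ("conserved" means matrix score > 0; the PSSM
partner residue is the reference residue at the aligned column — a PSSM
column has no single residue, so the reference is the defensible reading;
scoring against the column's max-scoring residue is available behind the
same machinery via the PSSM itself). Pairs involving 'X' contribute
nothing, which keeps every P_i ≥ 0. The fold-specific score divides the
positive positional mass by the query length, so appending unmatched
residues halves the score exactly — asserted in tests.

Structural similarity is the Pearson correlation of two profiles over the
collection's fold axes (manifest order is the single source of axis
order). When either profile has zero variance — e.g. a query with no
surviving alignments anywhere — the correlation is undefined and 0.0 is
returned ("no evidence of similarity"); this keeps all-against-all tables
NaN-free. Fold prediction is the argmax axis, ties to the earliest axis,
"unassigned" for all-zero profiles.

The strict preset (e-value 0.01, no coverage filter) is the default
throughout; the permissive preset (e-value 10¹⁰, coverage ≥ 0.80) trades
significance filtering for coverage filtering.

## Template selection

Entities are embedded as per-PSSM features: best surviving alignment's
(identity over aligned pairs) × (PSSM coverage), zero when nothing
survives — fractional scales, since Pearson is per-axis scale-invariant.
Clustering is agglomerative with distance 1 − Pearson; average linkage
(UPGMA) is the default because it is the standard choice for
correlation-based profiles (the linkage is configurable). Since no cut
criterion can be stated for a visual dendrogram inspection, selection is
operationalized as top-k (default 3) by Pearson similarity to the target,
ties broken by entity id after rounding similarities to 12 decimals; the
dendrogram is emitted (Newick) for inspection.

## Evaluation

ROC analysis pools all unordered pairs globally, sweeps every distinct
score as a threshold with ties counted as predicted positive, and reports
sensitivity TP/(TP+FN) against false-positive rate FP/(FP+TN) with
trapezoidal AUC (scikit-learn backed; a brute-force enumeration oracle is
kept in the tests). Top-k confusion classifies each query's k
highest-ranked partners; cross-method comparisons operate on unordered
pair sets.

## Synthetic benchmark generator

The generator emulates fold families divergent to the twilight zone. Per
fold: an ancestor drawn i.i.d. from the Robinson–Robinson background with
length ~ Normal(135, 90) clamped at ≥ 40 (the identity band needs ~1/n
resolution); a conservation mask of alternating geometric blocks
(conserved mean 8, variable mean 12) with conserved sites mutating at
relative rate 0.05 — the blocky, shared-within-fold conserved core is what
lets positively-scoring substitution structure survive at 20–30% identity,
as in real families; without site-rate heterogeneity repeated substitution
drives every column to background and the twilight zone carries no signal
at all. Substitutions are proposed from the Sinkhorn-balanced BLOSUM
conditional exchange distribution; indels (rate 0.02 per residue,
geometric(0.5) lengths, placed rate-proportionally, insertions from the
background) are applied first. Each mutant is driven into its target
identity band — measured with the package's own Needleman–Wunsch at the
10/0.5 settings, so generator and measured statistic agree — by a cheap
Hamming-proxy phase followed by NW-measured single steps; a band of
±0.03 around a target drawn uniformly in (0.20, 0.30) is the default.

All randomness flows from one integer seed through a single stream; runs
are byte-identical. The canonical study conditions are 8 folds,
2 seeds/fold, 15 homologs/seed, 5 held-out queries/fold.

What the generator does **not** emulate: real secondary-structure-aware
substitution preferences, domain shuffling or repeats, compositional bias,
phylogenetic correlation among family members (mutants are independent
given the ancestor), and realistic indel hotspots. Passing the recovery
tests therefore shows that the pipeline extracts shared conserved-core
signal at twilight-zone identity under a favorable, well-specified null —
not that it matches real-benchmark accuracy figures.

## Problem sizes and runtime choices

Tests and the acceptance script run the canonical 8-fold world (~300
sequences, 16 PSSMs, 40 queries; about a minute end-to-end on one CPU);
brute-force alignment oracles run at lengths ≤ 8 (exhaustive enumeration
for global; a memoized recursion over (i, j, gap-state) for local, itself
validated against substring enumeration at lengths ≤ 5). Library sizes
beyond ~10² folds are out of scope for the test suite, though nothing in
the implementation caps them.

## Known limitations

* Homolog placement by pairwise global alignment to the seed degrades as
  homolog–seed identity approaches the twilight zone; an iterative
  profile-based placement would be the natural upgrade.
* E-values inherit BLOSUM62-regime constants unless explicitly
  recalibrated per PSSM; they are filters, not calibrated probabilities.
* Multiple HSPs per (query, PSSM) are not collected; if a fold's signal is
  split across several disjoint alignments to one PSSM, only the best
  segment contributes.
* The 0.1 similarity calling threshold is a convention carried with the
  method, not refit to the synthetic world.
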