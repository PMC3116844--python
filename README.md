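# foldscan

Protein fold recognition with fold-specific PSSM libraries, for sequences in
the "twilight zone" of similarity (≲25% pairwise identity), where ordinary
alignment significance breaks down but structure is still conserved.

`foldscan` is aimed at structural bioinformaticians who need to assign a
fold to a divergent protein sequence, relate divergent sequences to each
other, or pick modeling templates, using nothing but amino-acid sequences
and a library of fold-labeled reference sets.

## The method

For each fold *F* (a SCOP-style structural class), a **fold-specific
library** is built: one position-specific scoring matrix (PSSM) per
reference (seed) sequence, constructed from the seed plus a redundancy-
filtered set of homologs (near-identical sequences at ≥90% identity to the
seed are removed, then a greedy sweep removes sequences at ≥40% mutual
identity). A query *q* of length *n* is locally aligned against every PSSM
in the library; alignments failing the e-value/coverage thresholds are
discarded (presets: *strict* = e-value ≤ 0.01, no coverage filter;
*permissive* = e-value ≤ 10¹⁰, coverage ≥ 80%). Each query residue *i* that
is identically or conservatively aligned (BLOSUM62 score > 0) to a PSSM
reference residue accumulates that score into its positional score *P·i*,
and the **fold-specific score** is

    S_F(q) = ( Σ_i max(P_i, 0) ) / n .

The vector of fold-specific scores over an ordered collection of fold
libraries is the query's **structural sequence profile**, and the
**structural similarity score** of two proteins is the Pearson correlation
*PC(X, Y)* of their profiles; pairs above 0.1 are conventionally called
structurally related. Fold assignment is the argmax axis of the profile.
Within a predicted fold, candidate templates and the target are embedded
as per-PSSM (identity × coverage) feature vectors, clustered hierarchically
(UPGMA, distance 1 − Pearson), and the templates most correlated with the
target are selected.

A synthetic-benchmark generator produces self-contained fold "worlds" —
ancestor sequences with conserved-core/variable-loop structure, mutated to
a controlled identity band — so the whole pipeline is testable without
external databases.

## Worked example

Simulate a small twilight-zone world, build its libraries, and call folds:

```
foldscan simulate --out world --seed 5 --folds 2 --seeds-per-fold 1 \
    --homologs-per-seed 2 --queries-per-fold 1
foldscan build-library --fold-id fold01 --seeds world/fold01/seeds.fasta \
    --homologs world/fold01/homologs --out lib01
foldscan build-library --fold-id fold02 --seeds world/fold02/seeds.fasta \
    --homologs world/fold02/homologs --out lib02
foldscan compile --libs lib01 --libs lib02 --out collection
foldscan predict --query world/queries.fasta --collection collection
```

which prints (query, fold call, best fold-specific score):

```
query	predicted_fold	best_score
fold01_q1	fold01	1.8103
fold02_q1	fold02	0.5395
```

Both held-out queries — each at only ~20–30% identity to its fold's
ancestor — are assigned to the correct fold; the score is the mean positive
BLOSUM62 conservation per residue accumulated from the fold's PSSMs (0 for
a fold with no surviving alignments). The same collection drives
`foldscan scan` (per-fold score table), `foldscan profile` (profile
matrix), `foldscan similarity` (all-against-all Pearson scores) and
`foldscan select-templates` (ranked templates plus a Newick dendrogram).

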