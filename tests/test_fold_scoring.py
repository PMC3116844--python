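import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import foldscan as fs
from foldscan.fold_scoring import (
    PositionalScoreTrack,
    ScanThresholds,
    StructuralSequenceProfile,
    pearson,
)
from foldscan.pairwise_align import KarlinAltschulParams, ProfileAlignment
from foldscan.seq_formats import RESIDUE_ORDER

from conftest import random_sequence


def _alignment(query_id="q", pssm_id="p", fold_id="f", pairs=((1, 1),),
               score=50.0, evalue=1e-5, coverage=1.0, plen=None):
    qs = [p[0] for p in pairs]
    ps = [p[1] for p in pairs]
    return ProfileAlignment(
        query_id=query_id, pssm_id=pssm_id, fold_id=fold_id,
        qstart=min(qs), qend=max(qs), pstart=min(ps), pend=max(ps),
        pairs=tuple(pairs), score=score, evalue=evalue, coverage=coverage,
    )


class TestThresholds:
    def test_presets(self):
        assert ScanThresholds.strict() == ScanThresholds(0.01, 0.0)
        assert ScanThresholds.permissive() == ScanThresholds(1e10, 0.80)

    def test_strict_filters_by_evalue(self):
        alns = [_alignment(evalue=1e-5), _alignment(evalue=0.5)]
        kept = [a for a in alns if ScanThresholds.strict().accepts(a)]
        assert len(kept) == 1 and kept[0].evalue == 1e-5

    def test_permissive_filters_by_coverage(self):
        aln = _alignment(evalue=1e-5, coverage=0.60)
        assert not ScanThresholds.permissive().accepts(aln)
        assert ScanThresholds.strict().accepts(aln)

    def test_boundary_values_accepted(self):
        # E == max_evalue and coverage == min_coverage both pass
        aln = _alignment(evalue=0.01, coverage=0.80)
        assert ScanThresholds.strict().accepts(aln)
        assert ScanThresholds.permissive().accepts(aln)

    def test_scan_empty_library_like_counting(self, blosum):
        # constructed alignment sets: exact keep-counts under both presets
        alns = [
            _alignment(pssm_id=f"p{i}", evalue=e, coverage=c)
            for i, (e, c) in enumerate(
                [(1e-5, 0.9), (0.009, 0.5), (0.5, 0.95), (1e3, 0.81), (9e9, 0.2)]
            )
        ]
        strict = sum(ScanThresholds.strict().accepts(a) for a in alns)
        permissive = sum(ScanThresholds.permissive().accepts(a) for a in alns)
        assert strict == 2   # 1e-5 and 0.009
        assert permissive == 3  # coverages 0.9, 0.95, 0.81


class TestPositionalScores:
    def test_identical_pair_scores_blosum_diagonal(self, blosum):
        q = fs.SequenceRecord(id="q", residues="LLLL")
        aln = _alignment(pairs=((2, 1),))
        track = fs.positional_scores(q, [aln], blosum, reference_lookup={"p": "L"})
        assert track.scores[1] == 4  # BLOSUM62 L:L
        assert track.scores[[0, 2, 3]].sum() == 0

    def test_negative_nonidentical_pair_contributes_nothing(self, blosum):
        q = fs.SequenceRecord(id="q", residues="L")
        aln = _alignment(pairs=((1, 1),))
        track = fs.positional_scores(q, [aln], blosum, reference_lookup={"p": "D"})
        assert track.scores[0] == 0  # BLOSUM62 L:D = -4, not conserved

    def test_conserved_pair_contributes_positive_score(self, blosum):
        q = fs.SequenceRecord(id="q", residues="L")
        aln = _alignment(pairs=((1, 1),))
        track = fs.positional_scores(q, [aln], blosum, reference_lookup={"p": "I"})
        assert track.scores[0] == blosum.score("L", "I") > 0

    def test_scores_sum_across_alignments(self, blosum):
        q = fs.SequenceRecord(id="q", residues="ALW")
        alns = [
            _alignment(pssm_id="p1", pairs=((2, 1),)),
            _alignment(pssm_id="p2", pairs=((2, 3),)),
        ]
        lookup = {"p1": "L", "p2": "XXL"}
        track = fs.positional_scores(q, alns, blosum, reference_lookup=lookup)
        assert track.scores[1] == 8

    def test_out_of_range_pair_rejected(self, blosum):
        q = fs.SequenceRecord(id="q", residues="AL")
        aln = _alignment(pairs=((3, 1),))
        with pytest.raises(ValueError, match="out of range"):
            fs.positional_scores(q, [aln], blosum, reference_lookup={"p": "L"})

    def test_nonnegative_on_random_scans(self, blosum, small_benchmark, small_collection):
        for q in small_benchmark.queries:
            for lib in small_collection:
                hits = fs.scan(q, lib, ScanThresholds.permissive())
                lookup = {p.id: p.reference.residues for p in lib.pssms}
                track = fs.positional_scores(q, hits, blosum, reference_lookup=lookup)
                assert np.all(track.scores >= 0)


class TestFoldSpecificScore:
    def test_all_zero(self):
        track = PositionalScoreTrack("q", "f", np.zeros(10))
        assert fs.fold_specific_score(track) == 0.0

    def test_direct_arithmetic(self):
        track = PositionalScoreTrack("q", "f", np.array([5.0, 0.0, 3.0]))
        assert fs.fold_specific_score(track) == pytest.approx(8.0 / 3.0)

    def test_appending_unmatched_residues_halves_score(self):
        P = np.array([5.0, 0.0, 3.0])
        s1 = fs.fold_specific_score(PositionalScoreTrack("q", "f", P))
        s2 = fs.fold_specific_score(
            PositionalScoreTrack("q", "f", np.concatenate([P, np.zeros(3)]))
        )
        assert s2 == pytest.approx(s1 / 2.0)


class TestStructuralProfile:
    def test_axis_order_contract(self, blosum, small_benchmark, small_collection):
        q = small_benchmark.queries[0]
        prof = fs.structural_profile(q, small_collection, blosum)
        assert prof.fold_ids == small_collection.fold_ids
        # permuting the collection permutes the vector identically
        reordered = fs.compile_collection(list(small_collection)[::-1])
        prof2 = fs.structural_profile(q, reordered, blosum)
        assert prof2.fold_ids == prof.fold_ids[::-1]
        assert np.allclose(prof2.values, prof.values[::-1])

    def test_true_fold_axis_positive(self, blosum, small_benchmark, small_collection):
        hits = 0
        for q in small_benchmark.queries:
            prof = fs.structural_profile(q, small_collection, blosum)
            idx = small_collection.fold_ids.index(small_benchmark.truth[q.id])
            if prof.values[idx] > 0:
                hits += 1
        assert hits >= len(small_benchmark.queries) - 1

    def test_monotone_in_added_alignment(self, blosum):
        # adding a positive-scoring alignment never decreases the fold score
        q = fs.SequenceRecord(id="q", residues="ALWK")
        base = [_alignment(pssm_id="p1", pairs=((1, 1),))]
        extra = base + [_alignment(pssm_id="p2", pairs=((3, 1),))]
        lookup = {"p1": "A", "p2": "W"}
        s_base = fs.fold_specific_score(
            fs.positional_scores(q, base, blosum, reference_lookup=lookup)
        )
        s_extra = fs.fold_specific_score(
            fs.positional_scores(q, extra, blosum, reference_lookup=lookup)
        )
        assert s_extra >= s_base


class TestStructuralSimilarity:
    @staticmethod
    def _profile(qid, values):
        return StructuralSequenceProfile(
            query_id=qid,
            fold_ids=tuple(f"f{i}" for i in range(len(values))),
            values=np.asarray(values, dtype=float),
        )

    def test_identity_and_anticorrelation(self):
        x = self._profile("x", [1, 2, 3])
        y = self._profile("y", [3, 2, 1])
        assert fs.structural_similarity(x, x) == pytest.approx(1.0)
        assert fs.structural_similarity(x, y) == pytest.approx(-1.0)

    def test_constant_profile_convention(self):
        x = self._profile("x", [2, 2, 2])
        y = self._profile("y", [1, 2, 3])
        assert fs.structural_similarity(x, y) == 0.0

    def test_axis_mismatch_rejected(self):
        x = self._profile("x", [1, 2, 3])
        y = StructuralSequenceProfile(
            query_id="y", fold_ids=("g0", "g1", "g2"), values=np.array([1.0, 2, 3])
        )
        with pytest.raises(ValueError, match="axes"):
            fs.structural_similarity(x, y)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_textbook_pearson(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        direct = np.sum((x - x.mean()) * (y - y.mean())) / (
            n * x.std() * y.std()
        )
        assert pearson(x, y) == pytest.approx(direct, abs=1e-12)
        assert pearson(x, y) == pytest.approx(scipy.stats.pearsonr(x, y)[0], abs=1e-9)


class TestPredictFold:
    @staticmethod
    def _profile(values):
        return StructuralSequenceProfile(
            query_id="q",
            fold_ids=tuple(f"f{i}" for i in range(len(values))),
            values=np.asarray(values, dtype=float),
        )

    def test_argmax(self):
        assert fs.predict_fold(self._profile([0.0, 0.5, 0.2])) == "f1"

    def test_all_zero_unassigned(self):
        assert fs.predict_fold(self._profile([0.0, 0.0])) == "unassigned"

    def test_tie_resolves_to_earliest_axis(self):
        assert fs.predict_fold(self._profile([0.5, 0.5])) == "f0"


class TestSimilarityMatrix:
    @staticmethod
    def _profiles(vectors):
        return [
            StructuralSequenceProfile(
                query_id=f"q{i}",
                fold_ids=tuple(f"f{k}" for k in range(len(v))),
                values=np.asarray(v, dtype=float),
            )
            for i, v in enumerate(vectors)
        ]

    def test_symmetric_and_self_excluded(self):
        profiles = self._profiles([[1, 0, 2], [0, 1, 2], [2, 1, 0]])
        table = fs.similarity_matrix(profiles)
        assert np.allclose(table.scores, table.scores.T)
        for qid in table.ids:
            ranking = table.ranking(qid)
            assert len(ranking) == 2
            assert qid not in [r[0] for r in ranking]

    def test_truth_labels_attached(self):
        profiles = self._profiles([[1, 0], [0, 1], [1, 0.1]])
        truth = {"q0": "a", "q1": "b", "q2": "a"}
        table = fs.similarity_matrix(profiles, truth=truth)
        assert table.labels[frozenset(("q0", "q2"))] is True
        assert table.labels[frozenset(("q0", "q1"))] is False
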