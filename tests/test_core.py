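import numpy as np
import pytest

import naive_oracle as oracle
from alncompare import (
    Alignment,
    Category,
    UndefinedScoreError,
    cell_equivalent,
    compare_alignments,
    cysteine_proportion,
    encode_occurrences,
    match_columns,
    overall_score,
    per_column_summaries,
    similarity_matrix,
)
from alncompare.core import AlignmentValidationError


class TestEncodeOccurrences:
    def test_repeated_residues_numbered_left_to_right(self):
        a = Alignment.from_rows(["x", "y"], ["AC-AG", "AAAAA"])
        enc = encode_occurrences(a)
        assert [enc.cell(0, i) for i in range(5)] == [
            ("A", 1), ("C", 1), None, ("A", 2), ("G", 1),
        ]
        assert [enc.cell(1, i) for i in range(5)] == [
            ("A", k) for k in range(1, 6)
        ]

    def test_all_gap_row_stays_gap(self):
        a = Alignment.from_rows(["x", "y"], ["ACG", "---"])
        enc = encode_occurrences(a)
        assert all(enc.cell(1, i) is None for i in range(3))

    def test_distinct_residues_all_first_occurrence(self):
        a = Alignment.from_rows(["x", "y"], ["ACGT", "TGCA"])
        enc = encode_occurrences(a)
        assert (enc.occ[enc.occ > 0] == 1).all()

    def test_row_cells_unique_and_degap_recoverable(self):
        a = Alignment.from_rows(["x", "y"], ["AAC-CA", "C--CCC"])
        enc = encode_occurrences(a)
        for x in range(2):
            cells = [enc.cell(x, i) for i in range(6) if enc.cell(x, i) is not None]
            assert len(set(cells)) == len(cells)
            assert "".join(sym for sym, _ in cells) == a.degapped()[x]


class TestCellEquivalent:
    def test_identical_non_gap(self):
        assert cell_equivalent(("A", 1), ("A", 1)) == 1

    def test_different_occurrence_of_same_residue(self):
        assert cell_equivalent(("A", 1), ("A", 2)) == 0

    def test_gaps_never_equivalent(self):
        assert cell_equivalent(None, None) == 0
        assert cell_equivalent(("A", 1), None) == 0


class TestSimilarityMatrix:
    def test_self_comparison_diagonal_is_occupancy(self):
        a = Alignment.from_rows(["x", "y", "z"], ["AC-G", "A-CG", "----"])
        enc = encode_occurrences(a)
        S = similarity_matrix(enc, enc)
        occupancy = (a.chars != "-").sum(axis=0) / a.n
        assert np.array_equal(np.diag(S), occupancy)

    def test_disjoint_alignments_give_zero_matrix(self):
        # no (symbol, occurrence) cell is shared in any row position
        p = encode_occurrences(Alignment.from_rows(["x", "y"], ["AA", "AG"]))
        q = encode_occurrences(Alignment.from_rows(["x", "y"], ["CC", "CT"]))
        assert (similarity_matrix(p, q) == 0).all()

    def test_row_count_mismatch_rejected(self):
        p = encode_occurrences(Alignment.from_rows(["x", "y"], ["AC", "CA"]))
        q = encode_occurrences(Alignment.from_rows(["x", "y", "z"], ["AC", "CA", "AA"]))
        with pytest.raises(AlignmentValidationError):
            similarity_matrix(p, q)

    def test_matches_triple_loop_oracle(self, rng):
        from conftest import random_pair

        for _ in range(25):
            ref, comp = random_pair(rng)
            S = similarity_matrix(encode_occurrences(ref), encode_occurrences(comp))
            rows_p = [ref.row_str(x) for x in range(ref.n)]
            rows_q = [comp.row_str(x) for x in range(comp.n)]
            expected = oracle.similarity(oracle.encode(rows_p), oracle.encode(rows_q))
            assert np.array_equal(S, expected)


class TestMatchColumns:
    def test_simple_argmax(self):
        mv = match_columns(np.array([[0.2, 0.9, 0.1]]))
        assert mv.indices[0] == 1
        assert not mv.tie_flags[0]

    def test_tie_broken_towards_diagonal(self):
        # columns 1 and 2 (0-based) tie for reference column 2
        S = np.array([[1.0, 0, 0], [0, 0.5, 0], [0, 0.5, 0.5]])
        mv = match_columns(S)
        assert list(mv.indices) == [0, 1, 2]
        assert list(mv.tie_flags) == [False, False, True]

    def test_all_zero_row_flagged_and_matched_by_index(self):
        S = np.zeros((3, 5))
        mv = match_columns(S)
        assert list(mv.indices) == [0, 1, 2]
        assert mv.tie_flags.all()


class TestWorkedExample:
    def test_full_comparison(self, worked_pair):
        res = compare_alignments(*worked_pair)
        assert np.array_equal(
            res.S, np.array([[1, 0, 0], [0, 0.5, 0], [0, 0.5, 0.5]])
        )
        assert list(res.match.indices) == [0, 1, 2]
        M, G, E, P = Category.MATCH, Category.CONSERVED_GAP, Category.MERGE, Category.SPLIT
        assert res.D.tolist() == [[M, M, M], [M, E, P]]
        assert np.array_equal(
            res.R,
            np.array(
                [[1, 0.5, 0.5], [0, 0, 0], [0, 0.5, 0], [0, 0, 0.5], [0, 0, 0]]
            ),
        )
        assert res.overall_score == pytest.approx(2 / 3)
        assert res.column_score == pytest.approx(1 / 3)

    def test_swap_merge_split_orientation(self, worked_pair):
        res = compare_alignments(*worked_pair, swap_merge_split=True)
        assert res.D[1, 1] == Category.SPLIT
        assert res.D[1, 2] == Category.MERGE

    def test_crossed_residues_are_shifts(self):
        from alncompare import MatchVector, dissimilarity_matrix

        # force each reference column against the *other* comparison column:
        # every cell pairs (A,1) with (C,1) or vice versa — all shifts
        enc = encode_occurrences(Alignment.from_rows(["x", "y"], ["AC", "CA"]))
        mv = MatchVector(
            indices=np.array([1, 0]), tie_flags=np.zeros(2, dtype=bool)
        )
        D = dissimilarity_matrix(enc, enc, mv)
        assert (D == Category.SHIFT).all()


class TestScores:
    def test_self_comparison_is_perfect(self):
        a = Alignment.from_rows(["x", "y"], ["AC--G", "A-C-G"])
        res = compare_alignments(a, a)
        assert res.overall_score == 1.0
        assert res.column_score == 1.0
        assert set(np.unique(res.D)) <= {Category.MATCH, Category.CONSERVED_GAP}

    def test_zero_matches_no_conserved_gaps(self):
        R = np.array([[0.0, 0.0], [0, 0], [0, 0], [0.5, 0.5], [0.5, 0.5]])
        assert overall_score(R) == 0.0

    def test_all_conserved_gaps_undefined(self):
        R = np.array([[0.0], [1.0], [0.0], [0.0], [0.0]])
        with pytest.raises(UndefinedScoreError):
            overall_score(R)


class TestPerColumnSummaries:
    def test_half_gap_column_normalises_to_one(self):
        R = np.array([[0.5], [0.5], [0.0], [0.0], [0.0]])
        s = per_column_summaries(R)
        assert s.match[0] == 1.0

    def test_mixed_column(self):
        R = np.array([[0.25], [0.5], [0.25], [0.0], [0.0]])
        s = per_column_summaries(R)
        assert s.match[0] == 0.5
        assert s.merge[0] == 0.5

    def test_all_conserved_gap_column_undefined(self):
        R = np.array([[0.0, 1.0], [1.0, 0.0], [0, 0], [0, 0], [0, 0]])
        s = per_column_summaries(R)
        assert not s.defined[0] and s.defined[1]
        assert np.isnan(s.match[0])


class TestCysteineProportion:
    def test_counts_per_column(self):
        a = Alignment.from_rows(
            ["w", "x", "y", "z"], ["CC", "C-", "CA", "CC"]
        )
        assert cysteine_proportion(a).tolist() == [1.0, 0.5]

    def test_nucleotide_c_is_counted_literally(self):
        a = Alignment.from_rows(["x", "y"], ["CAT", "CGT"])
        assert cysteine_proportion(a).tolist() == [1.0, 0.0, 0.0]


def test_validation_failure_yields_no_result():
    a = Alignment.from_rows(["x", "y"], ["ACG", "TTT"])
    b = Alignment.from_rows(["x", "y"], ["ACG", "TTA"])
    with pytest.raises(AlignmentValidationError):
        compare_alignments(a, b)
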