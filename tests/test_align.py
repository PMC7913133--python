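import numpy as np
import pytest
from Bio.Align import substitution_matrices

from conftest import random_protein
from oracles import brute_force_best_score, score_gapped_pair
from psykit.align import (
    AlignParams,
    extract_domain,
    load_matrix,
    nw_align,
    round_half_up,
    similarity_table,
)
from psykit.motifs import psy_strict_pattern, relaxed_five_residue_pattern
from psykit.seqio import PrecursorRecord
from psykit.simulate import PrecursorSimConfig, gen_precursors, mutate_motif


class TestMatrix:
    def test_vendored_blosum62_equals_reference(self):
        """Checksum test: the shipped matrix is entry-identical to Biopython's."""
        mine = load_matrix("BLOSUM62")
        ref = substitution_matrices.load("BLOSUM62")
        for a in ref.alphabet:
            for b in ref.alphabet:
                assert mine[(a, b)] == ref[a, b]

    def test_unknown_matrix_lists_available(self):
        with pytest.raises(ValueError, match="BLOSUM62"):
            load_matrix("PAM250")


class TestNwAlign:
    def test_self_alignment_is_perfect(self):
        r = nw_align("DYGDPSAN", "DYGDPSAN")
        assert r.identity_pct == 100.0
        assert r.similarity_pct == 100.0
        assert r.gaps_pct == 0.0
        matrix = load_matrix("BLOSUM62")
        assert r.score == sum(matrix[(c, c)] for c in "DYGDPSAN")

    @pytest.mark.parametrize("penalize_end_gaps", [False, True])
    def test_score_equals_brute_force_enumeration(self, py_rng, penalize_end_gaps):
        """DP optimality against exhaustive enumeration of all global alignments."""
        params = AlignParams(penalize_end_gaps=penalize_end_gaps)
        for _ in range(260):
            a = random_protein(py_rng, py_rng.randint(1, 6))
            b = random_protein(py_rng, py_rng.randint(1, 6))
            res = nw_align(a, b, params)
            assert res.score == pytest.approx(brute_force_best_score(a, b, params))
            # the reported alignment really achieves the reported score
            assert score_gapped_pair(res.aligned_a, res.aligned_b, params) == pytest.approx(res.score)

    def test_alignment_recovers_inputs(self, py_rng):
        for _ in range(50):
            a = random_protein(py_rng, py_rng.randint(5, 40))
            b = random_protein(py_rng, py_rng.randint(5, 40))
            res = nw_align(a, b)
            assert res.aligned_a.replace("-", "") == a
            assert res.aligned_b.replace("-", "") == b
            assert len(res.aligned_a) == len(res.aligned_b) == res.length

    def test_score_symmetry(self, py_rng):
        for _ in range(60):
            a = random_protein(py_rng, py_rng.randint(3, 30))
            b = random_protein(py_rng, py_rng.randint(3, 30))
            ab = nw_align(a, b)
            ba = nw_align(b, a)
            assert ab.score == pytest.approx(ba.score)
            assert ab.similarity_pct == pytest.approx(ba.similarity_pct)

    def test_identity_bounded_by_similarity_under_blosum62(self, py_rng):
        for _ in range(100):
            a = random_protein(py_rng, py_rng.randint(3, 50))
            b = random_protein(py_rng, py_rng.randint(3, 50))
            res = nw_align(a, b)
            assert res.identity_pct <= res.similarity_pct + 1e-12

    def test_deterministic_traceback(self, py_rng):
        a = random_protein(py_rng, 40)
        b = random_protein(py_rng, 35)
        first = nw_align(a, b)
        for _ in range(3):
            again = nw_align(a, b)
            assert (again.aligned_a, again.aligned_b) == (first.aligned_a, first.aligned_b)

    def test_matches_biopython_scores_on_longer_sequences(self, py_rng):
        """Independent cross-check of the affine model on non-toy lengths."""
        aligner = __import__("Bio.Align", fromlist=["PairwiseAligner"]).PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.5
        aligner.extend_gap_score = -0.5
        aligner.end_open_gap_score = 0.0
        aligner.end_extend_gap_score = 0.0
        for _ in range(40):
            a = random_protein(py_rng, py_rng.randint(10, 80))
            b = random_protein(py_rng, py_rng.randint(10, 80))
            assert nw_align(a, b).score == pytest.approx(aligner.score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            nw_align("", "DY")


class TestDomainExtraction:
    def test_embedded_strict_domain_extracted(self, strict_pattern, relaxed_pattern):
        rec = PrecursorRecord(id="t", sequence="G" * 60 + "DYGGGGANGGHGP" + "G" * 27)
        assert extract_domain(rec, strict_pattern, relaxed_pattern) == "DYGGGGANGGHGP"

    def test_no_motif_returns_none(self, strict_pattern, relaxed_pattern):
        rec = PrecursorRecord(id="t", sequence="G" * 80)
        assert extract_domain(rec, strict_pattern, relaxed_pattern) is None

    def test_strict_match_wins_regardless_of_relaxed_fallback(
        self, strict_pattern, relaxed_pattern
    ):
        rec = PrecursorRecord(id="t", sequence="G" * 60 + "DYGGGGANGGHGP" + "G" * 27)
        with_fallback = extract_domain(rec, strict_pattern, relaxed_pattern)
        without = extract_domain(rec, strict_pattern, None)
        assert with_fallback == without

    def test_relaxed_fallback_used_when_strict_absent(
        self, strict_pattern, relaxed_pattern
    ):
        rec = PrecursorRecord(id="t", sequence="G" * 60 + "DYGGGGGNGGHGP" + "G" * 27)
        assert extract_domain(rec, strict_pattern, relaxed_pattern) == "DYGGGGGNGGHGP"


class TestSimilarityTable:
    def test_copy_of_reference_scores_100_100(self):
        ref = PrecursorRecord(id="ref", sequence="G" * 60 + "DYGGGGANGGHGP" + "G" * 27)
        copy = PrecursorRecord(id="copy", sequence=ref.sequence)
        table = similarity_table(ref, [copy])
        assert table.rows == (("copy", 100.0, 100.0),)

    def test_reference_without_domain_rejected(self):
        ref = PrecursorRecord(id="ref", sequence="G" * 80)
        with pytest.raises(ValueError, match="no extractable domain"):
            similarity_table(ref, [])

    def test_domain_column_absent_when_no_motif(self):
        ref = PrecursorRecord(id="ref", sequence="G" * 60 + "DYGGGGANGGHGP" + "G" * 27)
        other = PrecursorRecord(id="o", sequence="G" * 80)
        table = similarity_table(ref, [other])
        (row,) = table.rows
        assert row[0] == "o" and row[2] is None

    def test_similarity_non_increasing_under_scripted_mutations(self):
        """Accumulating worst-partner substitutions in the domain never raises similarity."""
        records, truth = gen_precursors(PrecursorSimConfig(seed=42, n=1))
        record = records[0]
        start = int(truth.loc[0, "motif_start"])
        span = (start, start + 13)
        original_domain = record.sequence[start : start + 13]
        previous = 100.0
        for k in range(0, 14):
            rng = np.random.default_rng(999)  # same seed -> nested mutation sets
            mutated, positions = mutate_motif(record, k, rng, span=span)
            assert len(positions) == k
            domain = mutated.sequence[start : start + 13]
            pct = nw_align(original_domain, domain).similarity_pct
            assert pct <= previous + 1e-9
            previous = pct


def test_round_half_up_reporting_convention():
    assert round_half_up(84.615384) == 84.6
    assert round_half_up(92.25) == 92.3  # ties away from zero
    assert round_half_up(57.349) == 57.3
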