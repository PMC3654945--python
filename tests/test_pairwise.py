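"""Alignment engine, shuffle-null statistic, homology rule, clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_protein
from oracle_align import global_score_bruteforce, local_score_bruteforce
from tmsrep.pairwise import (
    AMINO_ACIDS,
    ComparisonScore,
    DegenerateNullError,
    HomologyCriteria,
    ScoringScheme,
    cluster_reduce,
    format_alignment,
    global_align,
    homology_call,
    local_align,
    local_score,
    shuffle_zscore,
)

SUB_ALPHABET = "ACDW"


class TestAlignment:
    def test_identity_alignment(self, scheme):
        aln = global_align("AAAA", "AAAA", scheme)
        assert aln.aligned_pairs == aln.identical == 4
        assert aln.pct_identity == 100.0
        assert aln.quality == 4 * scheme.score("A", "A")

    def test_symmetry(self, scheme):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a, b = random_protein(rng, 40), random_protein(rng, 35)
            assert global_align(a, b, scheme).quality == global_align(b, a, scheme).quality

    def test_empty_and_invalid_sequences_rejected(self, scheme):
        with pytest.raises(ValueError):
            global_align("", "AAA", scheme)
        with pytest.raises(ValueError):
            global_align("AB*", "AAA", scheme)  # '*' not a residue

    def test_x_scored_zero(self, scheme):
        aln = global_align("AXA", "AAA", scheme)
        assert aln.quality == 2 * scheme.score("A", "A")

    def test_local_equals_global_on_identical(self, scheme):
        rng = np.random.default_rng(2)
        a = random_protein(rng, 50)
        assert local_align(a, a, scheme).quality == global_align(a, a, scheme).quality

    def test_local_empty_when_all_negative(self, scheme):
        aln = local_align("RRRR", "DDDD", scheme)
        assert aln.is_empty and aln.quality == 0.0

    def test_local_recovers_planted_block(self, scheme):
        rng = np.random.default_rng(3)
        block = random_protein(rng, 30)
        a = random_protein(rng, 40) + block + random_protein(rng, 40)
        b = random_protein(rng, 25) + block + random_protein(rng, 25)
        aln = local_align(a, b, scheme)
        # the aligned region must contain the planted block on both rows
        assert aln.span_a[0] <= 41 and aln.span_a[1] >= 70
        assert aln.span_b[0] <= 26 and aln.span_b[1] >= 55
        assert aln.pct_identity > 90

    def test_global_matches_bruteforce_enumeration(self, scheme):
        """DP optimality against exhaustive enumeration of all alignments."""
        short = ["".join(p) for L in (1, 2) for p in itertools.product(SUB_ALPHABET, repeat=L)]
        for a in short[:8]:
            for b in short:
                expect = global_score_bruteforce(a, b, scheme.score, 8, 2)
                assert global_align(a, b, scheme).quality == pytest.approx(expect)
        rng = np.random.default_rng(4)
        for _ in range(40):
            a = "".join(rng.choice(list(SUB_ALPHABET), rng.integers(3, 7)))
            b = "".join(rng.choice(list(SUB_ALPHABET), rng.integers(3, 7)))
            expect = global_score_bruteforce(a, b, scheme.score, 8, 2)
            assert global_align(a, b, scheme).quality == pytest.approx(expect)

    def test_local_matches_bruteforce_enumeration(self, scheme):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = "".join(rng.choice(list(SUB_ALPHABET), rng.integers(1, 6)))
            b = "".join(rng.choice(list(SUB_ALPHABET), rng.integers(1, 6)))
            expect = local_score_bruteforce(a, b, scheme.score, 8, 2)
            assert local_score(a, b, scheme) == pytest.approx(expect)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet=AMINO_ACIDS, min_size=5, max_size=30),
        b=st.text(alphabet=AMINO_ACIDS, min_size=5, max_size=30),
    )
    def test_similarity_dominates_identity(self, a, b):
        """With positive diagonal scores every identity is also a similarity."""
        aln = global_align(a, b)
        assert aln.identical <= aln.similar <= aln.aligned_pairs


class TestScoringScheme:
    def test_gap_parameter_validation(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=1, gap_extend=2)

    def test_matrix_symmetric(self, scheme):
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                assert scheme.score(a, b) == scheme.score(b, a)


class TestShuffleZ:
    def test_self_comparison_is_highly_significant(self, scheme):
        rng = np.random.default_rng(7)
        a = random_protein(rng, 100)
        assert len(set(a)) >= 15
        cs = shuffle_zscore(a, a, scheme, n_shuffles=200, seed=1)
        assert cs.z > 10

    def test_deterministic_given_seed(self, scheme):
        rng = np.random.default_rng(8)
        a, b = random_protein(rng, 80), random_protein(rng, 70)
        z1 = shuffle_zscore(a, b, scheme, 50, seed=42)
        z2 = shuffle_zscore(a, b, scheme, 50, seed=42)
        assert z1.z == z2.z and z1.mu == z2.mu and z1.sigma == z2.sigma

    def test_degenerate_composition_raises(self, scheme):
        with pytest.raises(DegenerateNullError):
            shuffle_zscore("A" * 60, "A" * 60, scheme, n_shuffles=30, seed=0)

    def test_minimum_shuffles_enforced(self, scheme):
        with pytest.raises(ValueError):
            shuffle_zscore("ACDEF" * 10, "ACDEF" * 10, scheme, n_shuffles=10, seed=0)

    def test_null_z_small_on_unrelated(self, scheme):
        """Random 150-mers should score near zero, far below threshold."""
        rng = np.random.default_rng(9)
        zs = []
        for k in range(20):
            a, b = random_protein(rng, 150), random_protein(rng, 150)
            zs.append(shuffle_zscore(a, b, scheme, 100, seed=k).z)
        assert max(zs) < 6
        assert abs(float(np.mean(zs))) < 0.8

    def test_shift_cancellation(self):
        """z is invariant when a constant is added to every quality."""
        cs = ComparisonScore(quality=50, mu=20, sigma=5, z=6.0, n_shuffles=100, seed=0)
        shifted = (cs.quality + 7 - (cs.mu + 7)) / cs.sigma
        assert shifted == pytest.approx(cs.z)


class TestHomologyCall:
    CS = ComparisonScore(quality=500, mu=100, sigma=20, z=18.0, n_shuffles=100, seed=0)

    def _aln(self, scheme, n=120):
        rng = np.random.default_rng(10)
        a = random_protein(rng, n)
        return global_align(a, a, scheme)

    def test_pass_when_all_criteria_met(self, scheme):
        aln = self._aln(scheme)
        tms = [(10, 30), (50, 70), (90, 110)]
        dec = homology_call(self.CS, aln, tms, tms, HomologyCriteria())
        assert dec.passed and not dec.failed_criteria

    def test_fail_reasons_reported(self, scheme):
        aln = self._aln(scheme)
        tms = [(10, 30)]
        low = ComparisonScore(200, 150, 20, 9.9, 100, 0)
        assert homology_call(low, aln, tms, tms).failed_criteria == ["z_min"]
        short = self._aln(scheme, n=45)
        dec = homology_call(self.CS, short, [(5, 25)], [(5, 25)])
        assert "min_span" in dec.failed_criteria

    def test_tms_outside_span_fails_coverage(self, scheme):
        aln = self._aln(scheme, n=100)  # span 1..100
        dec = homology_call(self.CS, aln, [(10, 30)], [(150, 170)])
        assert "tms_overlap" in dec.failed_criteria

    def test_missing_annotation_raises(self, scheme):
        aln = self._aln(scheme)
        with pytest.raises(ValueError):
            homology_call(self.CS, aln, None, None, HomologyCriteria())


class TestClusterReduce:
    def test_identical_records_collapse(self):
        reps, cmap = cluster_reduce([("a", "ACDEFGHIKL" * 6), ("b", "ACDEFGHIKL" * 6)], 0.9)
        assert len(reps) == 1 and cmap["b"] == cmap["a"]

    def test_distant_records_stay_separate(self, scheme):
        rng = np.random.default_rng(11)
        a, b = random_protein(rng, 80), random_protein(rng, 80)
        identity = global_align(a, b, scheme).identical / 80
        assert identity < 0.5
        reps, _ = cluster_reduce([("a", a), ("b", b)], 0.9, scheme)
        assert len(reps) == 2

    def test_threshold_one_keeps_unique_sequences(self):
        recs = [("a", "ACDEFGHIKLMNPQRSTVWY"), ("b", "ACDEFGHIKLMNPQRSTVWY"),
                ("c", "ACDEFGHIKLMNPQRSTVWF")]
        reps, _ = cluster_reduce(recs, 1.0)
        assert sorted(r for r, _ in reps) == ["a", "c"]


class TestFormatAlignment:
    def test_match_line_marks(self, scheme):
        aln = global_align("ILKD", "ILRD", scheme)
        text = format_alignment(aln, "x", "y", scheme)
        lines = [l for l in text.splitlines() if l.strip()]
        match_line = lines[1].strip()
        # I-I and L-L identical, K-R close similarity (score 2), D-D identical
        assert match_line == "||:|"

    def test_blocks_carry_residue_numbers(self, scheme):
        rng = np.random.default_rng(12)
        a = random_protein(rng, 150)
        text = format_alignment(global_align(a, a, scheme), "p", "q", scheme)
        assert "    61" in text  # second 60-column block starts at residue 61

    def test_tms_markup_uppercases_only_tms(self, scheme):
        aln = global_align("ACDEFGHIKL", "ACDEFGHIKL", scheme)
        text = format_alignment(aln, "a", "b", scheme, tms_a=[(3, 5)], tms_b=[(3, 5)])
        row = text.splitlines()[0].split()[-1]
        assert row == "acDEFghikl"
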