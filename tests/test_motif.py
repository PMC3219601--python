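"""PWM parsing, log-odds scoring and cistrome screening."""

import numpy as np
import pytest

from pioneerscan.intervals import GenomicInterval, IntervalSet
from pioneerscan.motif import (
    PWM,
    best_hit_score,
    compare_screen_fractions,
    MotifScreenResult,
    parse_transfac,
    score_window,
    screen_cistrome,
    threshold_for_pvalue,
    window_scores,
    write_transfac,
)

from conftest import hypergeom_two_sided_p

TOY_RECORD = """\
ID TOY
XX
P0      A      C      G      T
01     10      0      0      0      A
02      0      0      0     10      T
XX
//
"""


class TestTransfac:
    def test_parse_toy_record(self):
        pwm = parse_transfac(TOY_RECORD)
        assert pwm.id == "TOY"
        assert len(pwm) == 2
        assert pwm.consensus == "AT"
        np.testing.assert_array_equal(pwm.counts[0], [10, 0, 0, 0])

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            parse_transfac(TOY_RECORD.replace("10      0", "-1      0", 1))

    def test_no_positions_rejected(self):
        with pytest.raises(ValueError):
            parse_transfac("ID EMPTY\nXX\n//\n")

    def test_roundtrip_random_pwm(self, rng):
        counts = rng.integers(0, 40, size=(9, 4)).astype(float)
        counts[0, 0] += 1  # avoid an all-zero row edge in consensus ties
        pwm = PWM(id="RND", counts=counts)
        back = parse_transfac(write_transfac(pwm))
        np.testing.assert_array_equal(back.counts, pwm.counts)
        assert back.id == "RND"


class TestScoring:
    def test_background_matching_pwm_scores_zero(self):
        # smoothed frequencies (1+1)/(4+4) = 0.25 = uniform background
        pwm = PWM(id="U", counts=np.ones((6, 4)))
        assert score_window("ACGTAC", pwm) == pytest.approx(0.0)
        assert score_window("NNNNNN", pwm) == pytest.approx(0.0)

    def test_degenerate_consensus_closed_form(self):
        # counts (10,0,0,0), pseudocount 1: p(A) = 11/14 against bg 0.25
        L = 5
        pwm = PWM(id="A", counts=np.tile([10.0, 0, 0, 0], (L, 1)))
        expected = L * np.log2((11 / 14) / 0.25)
        assert score_window("A" * L, pwm) == pytest.approx(expected)

    def test_wrong_length_rejected(self):
        pwm = PWM(id="U", counts=np.ones((4, 4)))
        with pytest.raises(ValueError):
            score_window("ACG", pwm)

    def test_reverse_complement_symmetry(self, rng):
        counts = rng.integers(0, 30, size=(7, 4)).astype(float)
        pwm = PWM(id="R", counts=counts)
        rc = pwm.reverse_complement()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(50):
            window = "".join(rng.choice(list("ACGT"), size=7))
            revcomp = "".join(comp[b] for b in reversed(window))
            assert score_window(window, pwm) == pytest.approx(
                score_window(revcomp, rc)
            )

    def test_window_scores_matches_explicit_loop(self, rng):
        counts = rng.integers(0, 30, size=(5, 4)).astype(float)
        pwm = PWM(id="R", counts=counts)
        seq = "".join(rng.choice(list("ACGTN"), size=80))
        got = window_scores(seq, pwm)
        expected = [score_window(seq[i : i + 5], pwm) for i in range(76)]
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestThreshold:
    def test_tail_probability_bound_holds_by_enumeration(self):
        pwm = PWM(id="T", counts=np.array([[8.0, 2, 1, 1]] * 4))
        thr = threshold_for_pvalue(pwm, pvalue=1e-2)
        # enumerate all 4^4 windows and their exact background probability
        from itertools import product

        tail = 0.0
        for word in product("ACGT", repeat=4):
            if score_window("".join(word), pwm) >= thr - 1e-9:
                tail += 0.25 ** 4
        assert tail <= 1e-2 + 1e-12
        # one discretisation step lower must exceed the target tail
        tail_lo = 0.0
        for word in product("ACGT", repeat=4):
            if score_window("".join(word), pwm) >= thr - 2e-3:
                tail_lo += 0.25 ** 4
        assert tail_lo > 1e-2


class TestScreen:
    def _toy_genome_and_peaks(self, rng, n_peaks=30, peak=40, L=5000):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=L))}
        starts = rng.choice(L - peak, size=n_peaks, replace=False)
        peaks = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s) + peak) for s in starts], "peaks"
        )
        return genome, peaks

    def test_threshold_extremes(self, rng):
        genome, peaks = self._toy_genome_and_peaks(rng)
        pwm = PWM(id="X", counts=rng.integers(0, 20, size=(6, 4)).astype(float))
        assert screen_cistrome(peaks, genome, pwm, np.inf).fraction == 0.0
        assert screen_cistrome(peaks, genome, pwm, -np.inf).fraction == 1.0

    def test_fraction_monotone_in_threshold(self, rng):
        genome, peaks = self._toy_genome_and_peaks(rng)
        pwm = PWM(id="X", counts=rng.integers(0, 20, size=(6, 4)).astype(float))
        fractions = [
            screen_cistrome(peaks, genome, pwm, thr).fraction
            for thr in np.linspace(-5, 10, 8)
        ]
        assert all(x >= y for x, y in zip(fractions, fractions[1:]))

    def test_strand_symmetric_detection(self, rng):
        pwm = PWM(id="M", counts=np.tile([0.0, 0, 0, 20], (6, 1)))  # TTTTTT
        base = "ACG" * 20
        genome = {
            "fwd": base + "TTTTTT" + base,
            "rev": base + "AAAAAA" + base,  # reverse complement of the motif
        }
        thr = 5.0
        for chrom in genome:
            peaks = IntervalSet([GenomicInterval(chrom, 50, 80)], "p")
            assert screen_cistrome(peaks, genome, pwm, thr).n_with_hit == 1

    def test_peak_outside_genome_named_in_error(self):
        genome = {"chr1": "ACGT" * 10}
        peaks = IntervalSet([GenomicInterval("chr1", 30, 60)], "p")
        pwm = PWM(id="X", counts=np.ones((4, 4)))
        with pytest.raises(ValueError, match="chr1:30-60"):
            screen_cistrome(peaks, genome, pwm, 0.0)


class TestCompareFractions:
    def test_identical_proportions_p_one(self):
        a = MotifScreenResult(100, 85, 0.0)
        assert compare_screen_fractions(a, a) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        a = MotifScreenResult(10, 9, 0.0)
        b = MotifScreenResult(10, 1, 0.0)
        assert compare_screen_fractions(a, b) == pytest.approx(
            hypergeom_two_sided_p(9, 1, 1, 9), rel=1e-9
        )

    def test_large_separation_extremely_significant(self):
        a = MotifScreenResult(5000, 4250, 0.0)
        b = MotifScreenResult(5000, 2000, 0.0)
        assert compare_screen_fractions(a, b) < 1e-50
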