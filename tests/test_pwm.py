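"""PWM construction, scoring, exact p-values, and strand-aware scanning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crmscreen.pwm import (
    build_pwm,
    reverse_complement,
    scan_sequence,
    score_distribution,
    score_window,
)

from conftest import enumerate_null, sharp_counts

GRAN = 1e-3


class TestBuildPwm:
    def test_uniform_counts_give_flat_pwm(self):
        pwm = build_pwm(np.full((4, 4), 5.0))
        assert np.allclose(pwm.probs, 0.25)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_pseudocount_arithmetic(self):
        # counts (10,0,0,0), pseudocount 0.1, uniform background:
        # prob_A = (10 + 0.1*0.25) / 10.1, others (0 + 0.025) / 10.1
        pwm = build_pwm(np.array([[10.0, 0, 0, 0]]), pseudocount=0.1)
        assert pwm.probs[0, 0] == pytest.approx(10.025 / 10.1)
        assert pwm.probs[0, 1] == pytest.approx(0.025 / 10.1)

    def test_probability_matrix_rescaled_to_100(self):
        probs = np.array([[0.7, 0.1, 0.1, 0.1]])
        pwm = build_pwm(probs, pseudocount=0.1)
        expected_a = (70.0 + 0.025) / 100.1
        assert pwm.probs[0, 0] == pytest.approx(expected_a)

    def test_mixed_count_probability_rows_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            build_pwm(np.array([[0.7, 0.1, 0.1, 0.1], [10, 0, 0, 0]]))

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_pseudocount_rejected(self, bad):
        with pytest.raises(ValueError):
            build_pwm(np.eye(4) * 10 + 1, pseudocount=bad)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(np.array([[1.0, 1, 1, 1], [0, 0, 0, 0]]))


class TestScoreWindow:
    def test_flat_pwm_scores_zero_everywhere(self):
        pwm = build_pwm(np.full((6, 4), 3.0))
        assert score_window(pwm, "ACGTAC") == pytest.approx(0.0)

    def test_consensus_score_is_sum_of_lookups(self):
        pwm = build_pwm(sharp_counts("ACG"))
        expected = pwm.log_odds[0, 0] + pwm.log_odds[1, 1] + pwm.log_odds[2, 2]
        assert score_window(pwm, "ACG") == pytest.approx(expected)

    def test_length_mismatch_and_n_rejected(self, sharp_pwm):
        with pytest.raises(ValueError):
            score_window(sharp_pwm, "ACGT")
        with pytest.raises(ValueError, match="N"):
            score_window(sharp_pwm, "TTTGNCTTT")


class TestScoreDistribution:
    def test_support_bounds(self, sharp_pwm):
        dist = score_distribution(sharp_pwm)
        assert dist.pvalue(sharp_pwm.min_score()) == pytest.approx(1.0)
        assert dist.pvalue(sharp_pwm.max_score() + 1.0) == 0.0

    def test_pmf_sums_to_one_and_sf_monotone(self, rng):
        counts = rng.integers(1, 40, size=(7, 4)).astype(float)
        dist = score_distribution(build_pwm(counts))
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(dist.sf) <= 1e-15)

    @pytest.mark.parametrize("L", [2, 4, 6, 8])
    def test_survival_matches_exhaustive_enumeration(self, L, rng):
        """DP p-values agree with 4^L enumeration within one granularity bin."""
        counts = rng.integers(0, 30, size=(L, 4)).astype(float) + 0.5
        pwm = build_pwm(counts)
        dist = score_distribution(pwm, GRAN)
        _, scores, p_exact = enumerate_null(pwm)
        for s in rng.choice(scores, size=min(40, len(scores)), replace=False):
            p_dp = dist.pvalue(float(s))
            lo = p_exact(float(s) + L * GRAN)
            hi = p_exact(float(s) - L * GRAN)
            assert lo - 1e-12 <= p_dp <= hi + 1e-12


class TestScanSequence:
    def test_planted_consensus_found_on_both_strands(self, sharp_pwm, rng):
        cons = sharp_pwm.consensus
        bg = "".join(rng.choice(list("ACGT"), size=300))
        seq = bg[:100] + cons + bg[109:]
        hits = scan_sequence(seq, sharp_pwm, p_threshold=1e-4)
        assert [(h.start, h.strand) for h in hits] == [(101, "+")]
        seq_rc = bg[:100] + reverse_complement(cons) + bg[109:]
        hits_rc = scan_sequence(seq_rc, sharp_pwm, p_threshold=1e-4)
        assert [(h.start, h.strand) for h in hits_rc] == [(101, "-")]

    def test_threshold_one_counts_every_window(self, sharp_pwm):
        seq = "TTTGACTTT"  # exactly one window per strand
        assert len(scan_sequence(seq, sharp_pwm, p_threshold=1.0, strands="forward")) == 1
        assert len(scan_sequence(seq, sharp_pwm, p_threshold=1.0, strands="both")) == 2

    def test_sequence_shorter_than_motif_is_empty(self, sharp_pwm):
        assert scan_sequence("ACGT", sharp_pwm) == []

    def test_windows_with_n_skipped(self, sharp_pwm):
        seq = "TTTGNCTTT" + "TTTGACTTT"
        hits = scan_sequence(seq, sharp_pwm, p_threshold=1e-4)
        assert [(h.start, h.strand) for h in hits] == [(10, "+")]

    def test_revcomp_scan_mirrors_hits(self, rng):
        """Scanning the reverse complement swaps strands and mirrors coordinates."""
        counts = rng.integers(1, 50, size=(6, 4)).astype(float)
        pwm = build_pwm(counts, motif_id="m")
        seq = "".join(rng.choice(list("ACGT"), size=400))
        fwd = scan_sequence(seq, pwm, p_threshold=5e-2)
        rev = scan_sequence(reverse_complement(seq), pwm, p_threshold=5e-2)
        n = len(seq)
        mirrored = sorted(
            (n - h.stop + 1, {"+": "-", "-": "+"}[h.strand], round(h.score, 6), round(h.p_value, 12))
            for h in rev
        )
        original = sorted((h.start, h.strand, round(h.score, 6), round(h.p_value, 12)) for h in fwd)
        assert mirrored == original

    def test_hits_against_per_window_brute_force(self, rng):
        """Hit set equals exhaustive per-window scoring at the same threshold."""
        counts = rng.integers(0, 25, size=(5, 4)).astype(float) + 0.5
        pwm = build_pwm(counts)
        _, _, p_exact = enumerate_null(pwm)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        thresh = 1e-2
        hits = {(h.start, h.strand) for h in scan_sequence(seq, pwm, p_threshold=thresh)}
        must_find, allowed = set(), set()
        for strand in "+-":
            for i in range(len(seq) - pwm.length + 1):
                w = seq[i : i + pwm.length]
                if strand == "-":
                    w = reverse_complement(w)
                s = score_window(pwm, w)
                if p_exact(s + pwm.length * GRAN) <= thresh:  # lower bound on discretised p
                    allowed.add((i + 1, strand))
                if p_exact(s - pwm.length * GRAN) <= thresh:  # upper bound on discretised p
                    must_find.add((i + 1, strand))
        assert must_find <= hits <= allowed

    def test_minus_strand_hit_reports_revcomp_window(self, sharp_pwm):
        cons = sharp_pwm.consensus
        seq = "GG" + reverse_complement(cons) + "GG"
        (hit,) = scan_sequence(seq, sharp_pwm, p_threshold=1e-4)
        assert hit.matched_sequence == cons
        assert (hit.start, hit.stop) == (3, 11)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_pvalue_positive_and_bounded(seed):
    """Occurrence p-values always lie in (0, 1]."""
    rng = np.random.default_rng(seed)
    pwm = build_pwm(rng.integers(1, 20, size=(4, 4)).astype(float))
    dist = score_distribution(pwm)
    for s in rng.uniform(pwm.min_score() - 1, pwm.max_score(), size=10):
        assert 0.0 < dist.pvalue(float(s)) <= 1.0
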