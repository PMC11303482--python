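import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atacmotif import (
    BackgroundModel,
    GenomeSequence,
    PositionCountMatrix,
    build_pwm,
    calibrate_threshold,
    peaks_with_motif,
    reverse_complement,
    scan_sequence,
)
from atacmotif.types import GenomicInterval

from conftest import enumerate_tail, naive_scan


def _pcm(cols, name="m"):
    return PositionCountMatrix(np.array(cols, dtype=float).T, motif_name=name)


class TestBuildPwm:
    def test_uniform_column_is_uninformative(self):
        pwm = build_pwm(_pcm([[1, 1, 1, 1]]), BackgroundModel.uniform(), pseudocount=1.0)
        assert np.allclose(pwm.weights, 0.0)

    def test_hand_derived_log_odds(self):
        # f_A = (8 + 1*0.25)/9, weight = log2(f/0.25)
        pwm = build_pwm(_pcm([[8, 0, 0, 0]]), BackgroundModel.uniform(), pseudocount=1.0)
        assert pwm.weights[0, 0] == pytest.approx(np.log2((8.25 / 9) / 0.25), abs=1e-10)
        assert pwm.weights[0, 0] == pytest.approx(1.8745, abs=5e-4)
        assert pwm.weights[1, 0] == pytest.approx(-3.1699, abs=5e-4)

    def test_count_scaling_invariant_as_pseudocount_vanishes(self):
        col = [6, 2, 1, 1]
        small = 1e-9
        w1 = build_pwm(_pcm([col]), pseudocount=small).weights
        w2 = build_pwm(_pcm([[4 * c for c in col]]), pseudocount=small).weights
        assert np.allclose(w1, w2, atol=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_pwm(_pcm([[1, 1, 1, 1]]), pseudocount=0.0)
        with pytest.raises(ValueError):
            PositionCountMatrix(np.zeros((4, 2)))


class TestCalibration:
    def test_length_one_consensus_a(self):
        pwm = calibrate_threshold(
            build_pwm(_pcm([[10, 1, 1, 1]]), BackgroundModel.uniform()), alpha=0.25
        )
        passing = [b for b in "ACGT" if scan_sequence(pwm, b, both_strands=False)]
        assert passing == ["A"]
        # any threshold in (weight_C, weight_A] admits exactly {A}
        assert pwm.weights[1, 0] < pwm.threshold <= pwm.weights[0, 0] + 2e-3

    def test_alpha_one_admits_every_word(self):
        pwm = calibrate_threshold(build_pwm(_pcm([[9, 3, 2, 1], [1, 1, 1, 17]])), alpha=1.0)
        assert pwm.threshold <= pwm.min_score
        for w in ("AA", "TT", "CG", "GC"):
            assert scan_sequence(pwm, w, both_strands=False), w

    @pytest.mark.parametrize("L", [2, 5, 8])
    @pytest.mark.parametrize("gc", [0.5, 0.3], ids=["uniform-bg", "skewed-bg"])
    def test_dp_tail_matches_exhaustive_enumeration(self, L, gc):
        rng = np.random.default_rng(L * 100 + int(gc * 10))
        counts = rng.integers(1, 40, size=(4, L)).astype(float)
        bg = BackgroundModel.from_gc(gc)
        g = 1e-3
        for alpha in (1e-2, 1e-3):
            pwm = calibrate_threshold(
                build_pwm(PositionCountMatrix(counts), bg), alpha=alpha, granularity=g
            )
            # sandwich: exact tail at threshold +/- L*g brackets the DP tail
            upper = enumerate_tail(pwm.weights, bg, pwm.threshold)
            lower = enumerate_tail(pwm.weights, bg, pwm.threshold + L * g)
            assert lower <= pwm.attained_p <= upper
            assert upper <= alpha + 1e-12 or lower <= alpha  # calibration honours alpha

    def test_threshold_monotone_in_alpha(self, sox9_pwm):
        from atacmotif.simulate import sox9_synthetic_pcm

        base = build_pwm(sox9_synthetic_pcm(), BackgroundModel.uniform())
        alphas = [1e-5, 1e-4, 1e-3, 1e-2]
        thresholds = [
            calibrate_threshold(build_pwm(sox9_synthetic_pcm(), BackgroundModel.uniform()), a).threshold
            for a in alphas
        ]
        assert thresholds == sorted(thresholds, reverse=True)

    def test_alpha_out_of_range(self, sox9_pwm):
        with pytest.raises(ValueError):
            calibrate_threshold(build_pwm(_pcm([[5, 1, 1, 1]])), alpha=0.0)


class TestScanner:
    def test_uncalibrated_pwm_rejected(self):
        pwm = build_pwm(_pcm([[5, 1, 1, 1]]))
        with pytest.raises(ValueError, match="calibrat"):
            scan_sequence(pwm, "ACGT")

    def test_planted_consensus_found_once(self, sox9_pwm):
        rng = np.random.default_rng(0)
        bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
        seq = bg[:7] + sox9_pwm.consensus + bg[7:]
        plus_hits = [h for h in scan_sequence(sox9_pwm, seq) if h.strand == "+"]
        assert [h.start for h in plus_hits] == [7]

    def test_reverse_complement_reported_on_minus(self, sox9_pwm):
        seq = "TTT" + reverse_complement(sox9_pwm.consensus) + "TTT"
        hits = scan_sequence(sox9_pwm, seq)
        assert [(h.start, h.strand) for h in hits] == [(3, "-")]

    def test_all_n_sequence_has_no_hits(self, sox9_pwm):
        assert scan_sequence(sox9_pwm, "N" * 100) == []

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_scanner_equals_naive_oracle(self, sox9_pwm, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGTN"))[rng.choice(5, 300, p=[0.24, 0.24, 0.24, 0.24, 0.04])])
        got = [(h.start, h.strand) for h in scan_sequence(sox9_pwm, seq)]
        want = sorted((s, strand) for s, strand, _ in naive_scan(sox9_pwm, seq))
        assert got == want

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_strand_symmetry(self, sox9_pwm, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        # plant on both strands so the property is exercised on non-empty sets
        seq = sox9_pwm.consensus + seq + reverse_complement(sox9_pwm.consensus)
        fwd = scan_sequence(sox9_pwm, seq)
        rc = scan_sequence(sox9_pwm, reverse_complement(seq))
        L, n = sox9_pwm.length, len(seq)
        reflected = sorted(
            (n - h.end, "+" if h.strand == "-" else "-") for h in rc
        )
        assert sorted((h.start, h.strand) for h in fwd) == reflected

    def test_hit_count_monotone_in_alpha(self):
        from atacmotif.simulate import sox9_synthetic_pcm

        rng = np.random.default_rng(11)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20000)])
        counts = []
        for alpha in (1e-4, 1e-3, 1e-2):
            pwm = calibrate_threshold(
                build_pwm(sox9_synthetic_pcm(), BackgroundModel.uniform()), alpha
            )
            counts.append(len(scan_sequence(pwm, seq)))
        assert counts == sorted(counts)


class TestPeaksWithMotif:
    def test_planted_flags(self, sox9_pwm):
        rng = np.random.default_rng(5)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        cons = sox9_pwm.consensus
        seq = base[:40] + cons + base[49:140] + base[140:240] + cons + base[249:]
        genome = GenomeSequence({"chr1": seq})
        peaks = [
            GenomicInterval("chr1", 20, 80, name="p1"),
            GenomicInterval("chr1", 100, 180, name="p2"),
            GenomicInterval("chr1", 220, 280, name="p3"),
        ]
        flags, count, hits = peaks_with_motif(peaks, genome, sox9_pwm, collect_hits=True)
        assert list(flags) == [True, False, True] and count == 2
        assert set(hits) == {"p1", "p3"}

    def test_empty_peak_list(self, sox9_pwm, toy_genome):
        flags, count, _ = peaks_with_motif([], toy_genome, sox9_pwm)
        assert count == 0 and flags.size == 0

    def test_out_of_bounds_peak_named_in_error(self, sox9_pwm, toy_genome):
        bad = GenomicInterval("chr1", 0, toy_genome.lengths["chr1"] + 10, name="runaway")
        with pytest.raises(ValueError, match="runaway"):
            peaks_with_motif([bad], toy_genome, sox9_pwm)

    def test_batch_equals_per_peak_scan(self, sox9_pwm, toy_genome):
        rng = np.random.default_rng(3)
        peaks = []
        for k in range(60):
            s = int(rng.integers(0, 4800))
            peaks.append(GenomicInterval("chr1", s, s + 120, name=f"p{k}"))
        flags, _, _ = peaks_with_motif(peaks, toy_genome, sox9_pwm)
        loop = [
            bool(scan_sequence(sox9_pwm, toy_genome.fetch_interval(p))) for p in peaks
        ]
        assert list(flags) == loop
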