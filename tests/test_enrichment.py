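import numpy as np
import pytest

from atacmotif import (
    BackgroundModel,
    GenomeSequence,
    GenomicInterval,
    MotifEnrichmentTest,
    build_pwm,
    calibrate_threshold,
    motif_enrichment,
    motif_fraction_summary,
    multi_tf_enrichment,
    sample_background_regions,
)
from atacmotif.simulate import (
    generate_genome,
    generate_peaks,
    plant_motifs,
    sox9_synthetic_pcm,
)


def _pwm_for(genome, alpha=1e-4):
    return calibrate_threshold(
        build_pwm(sox9_synthetic_pcm(), BackgroundModel.from_genome(genome)), alpha=alpha
    )


class TestBackgroundSampling:
    def test_forced_placement_single_position(self):
        genome = GenomeSequence({"chr1": "ACGT" * 250})
        samples = sample_background_regions(genome, [1000], n_perm=5, seed=1)
        for s in samples:
            (region,) = s.regions
            assert (region.start, region.end) == (0, 1000)

    def test_determinism_under_seed(self, toy_genome):
        a = sample_background_regions(toy_genome, [100] * 20, n_perm=4, seed=9)
        b = sample_background_regions(toy_genome, [100] * 20, n_perm=4, seed=9)
        for sa, sb in zip(a, b):
            assert [(r.start, r.end) for r in sa.regions] == [
                (r.start, r.end) for r in sb.regions
            ]

    def test_sampled_gc_matches_genome_gc(self):
        genome = generate_genome(1, 400_000, gc=0.41, seed=3)
        samples = sample_background_regions(genome, [200] * 50, n_perm=40, seed=2)
        gcs = [
            (seq.count("G") + seq.count("C")) / len(seq)
            for s in samples
            for seq in (genome.fetch_interval(r) for r in s.regions)
        ]
        # 2000 regions x 200 bp: binomial SE on the mean ~ 0.0008
        assert np.mean(gcs) == pytest.approx(0.41, abs=0.01)

    def test_exclusions_are_avoided(self, toy_genome):
        exclusions = [GenomicInterval("chr1", 0, 4000)]
        samples = sample_background_regions(
            toy_genome, [50] * 10, n_perm=20, seed=5, exclusions=exclusions
        )
        for s in samples:
            for r in s.regions:
                assert r.start >= 4000

    def test_gc_match_tolerance_respected(self):
        genome = generate_genome(1, 200_000, gc=0.5, seed=4)
        targets = np.array([0.6] * 10)
        samples = sample_background_regions(
            genome, [150] * 10, n_perm=5, seed=6, gc_match=0.05, gc_targets=targets
        )
        for s in samples:
            for r, t in zip(s.regions, targets):
                seq = genome.fetch_interval(r)
                gc = (seq.count("G") + seq.count("C")) / len(seq)
                assert abs(gc - t) <= 0.05 + 1e-9

    def test_oversized_region_errors(self, toy_genome):
        with pytest.raises(ValueError):
            sample_background_regions(toy_genome, [10_000], n_perm=1)


class TestEnrichment:
    @staticmethod
    @pytest.fixture(scope="class")
    def planted():
        genome = generate_genome(1, 300_000, gc=0.41, seed=10)
        peaks = generate_peaks(genome, 400, 300, 50, seed=11)
        pwm = _pwm_for(genome)
        mutated, truth = plant_motifs(genome, peaks, pwm, target_fold=2.5, seed=12)
        return mutated, peaks, pwm, truth

    def test_reproducible_bit_identical(self, planted):
        genome, peaks, pwm, _ = planted
        r1 = motif_enrichment(peaks, genome, pwm, n_perm=50, seed=7)
        r2 = motif_enrichment(peaks, genome, pwm, n_perm=50, seed=7)
        assert (r1.null_counts == r2.null_counts).all()
        assert r1.to_dict() == r2.to_dict()

    def test_planted_fold_recovered(self, planted):
        genome, peaks, pwm, truth = planted
        res = MotifEnrichmentTest(peaks, genome, pwm, exclusions=peaks).fit(
            n_perm=300, seed=8
        )
        assert res.fold_enrichment == pytest.approx(2.5, rel=0.2)
        assert res.empirical_p <= 0.01

    def test_empirical_p_never_zero_and_bounds(self, planted):
        genome, peaks, pwm, _ = planted
        res = motif_enrichment(peaks, genome, pwm, n_perm=40, seed=3)
        assert 0 < res.empirical_p <= 1
        assert res.empirical_p >= 1 / 41
        assert 0 <= res.observed_count <= res.n_peaks

    def test_zero_observed_gives_fold_zero_p_one(self):
        # peak of all N never contains a motif; nulls drawn from real sequence do
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30_000)])
        cons = sox9_synthetic_pcm().consensus
        seq = (cons + "TTTT") * 200 + seq  # motif-rich so null_mean > 0
        genome = GenomeSequence({"chr1": "N" * 500 + seq})
        pwm = calibrate_threshold(
            build_pwm(sox9_synthetic_pcm(), BackgroundModel.from_gc(0.5)), 1e-4
        )
        peaks = [GenomicInterval("chr1", 0, 400, name="n_peak")]
        res = motif_enrichment(peaks, genome, pwm, n_perm=99, seed=1)
        assert res.observed_count == 0
        assert res.fold_enrichment == 0.0
        assert res.empirical_p == 1.0

    def test_summary_contains_key_numbers(self, planted):
        genome, peaks, pwm, _ = planted
        res = motif_enrichment(peaks, genome, pwm, n_perm=20, seed=2)
        text = res.summary()
        assert str(res.observed_count) in text and "fold enrichment" in text


class TestMultiTf:
    @staticmethod
    @pytest.fixture(scope="class")
    def scene():
        genome = generate_genome(1, 200_000, gc=0.41, seed=20)
        peaks = generate_peaks(genome, 250, 300, 50, seed=21)
        pwm = _pwm_for(genome)
        mutated, _ = plant_motifs(genome, peaks, pwm, target_fold=2.0, seed=22)
        from atacmotif.datasets import example_motifs

        bg = BackgroundModel.from_genome(mutated)
        pwms = {
            name: calibrate_threshold(build_pwm(pcm, bg), alpha=1e-4)
            for name, pcm in example_motifs().items()
        }
        return mutated, peaks, pwms

    def test_planted_tf_ranks_first(self, scene):
        genome, peaks, pwms = scene
        table = multi_tf_enrichment(peaks, genome, pwms, n_perm=100, seed=5)
        assert table.iloc[0]["tf"] == "SOX9"
        assert table["fold"].is_monotonic_decreasing

    def test_single_tf_reduces_to_motif_enrichment(self, scene):
        genome, peaks, pwms = scene
        table = multi_tf_enrichment(
            peaks, genome, {"SOX9": pwms["SOX9"]}, n_perm=60, seed=9
        )
        single = motif_enrichment(peaks, genome, pwms["SOX9"], n_perm=60, seed=9)
        row = table.iloc[0]
        assert row["observed"] == single.observed_count
        assert row["fold"] == pytest.approx(single.fold_enrichment)
        assert row["empirical_p"] == pytest.approx(single.empirical_p)

    def test_motif_order_invariance(self, scene):
        genome, peaks, pwms = scene
        fwd = multi_tf_enrichment(peaks, genome, pwms, n_perm=40, seed=4)
        rev = multi_tf_enrichment(
            peaks, genome, dict(reversed(list(pwms.items()))), n_perm=40, seed=4
        )
        assert fwd.to_dict() == rev.to_dict()

    def test_duplicate_names_error(self, scene):
        genome, peaks, pwms = scene
        with pytest.raises(ValueError, match="at least one"):
            multi_tf_enrichment(peaks, genome, {}, n_perm=10, seed=1)


class TestFractionSummary:
    @pytest.mark.parametrize(
        "n_true, n, expected",
        [(847, 3633, (847, 23)), (0, 100, (0, 0)), (40, 40, (40, 100))],
        ids=["headline", "none", "all"],
    )
    def test_rounding(self, n_true, n, expected):
        flags = [True] * n_true + [False] * (n - n_true)
        assert motif_fraction_summary(flags) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            motif_fraction_summary([])
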