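"""Permutation test for motif enrichment in a peak set.

The statistic is the number of peaks containing at least one motif match.
Its null distribution is built by repeatedly placing a length-matched set of
random regions on the genome (optionally avoiding an exclusion list, and
optionally GC-matched to the observed peaks) and counting motif-containing
regions in each sample. Fold enrichment is observed / null mean, and the
empirical p-value uses the add-one permutation estimator, which can never
report zero.

The test is exposed both as a statsmodels-style model/results pair
(:class:`MotifEnrichmentTest` / :class:`EnrichmentResult`) and as the plain
functions :func:`motif_enrichment` and :func:`multi_tf_enrichment`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import GenomeScanIndex, PositionWeightMatrix, peaks_with_motif
from .types import GenomeSequence, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "NullSample",
    "EnrichmentResult",
    "MotifEnrichmentTest",
    "sample_background_regions",
    "motif_enrichment",
    "multi_tf_enrichment",
    "motif_fraction_summary",
]


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

@dataclass
class NullSample:
    """One permutation's random region set, length-matched to the peaks."""

    regions: list[GenomicInterval]
    motif_flag_count: int | None = None


class _Sampler:
    """Vectorised placement of length-matched random regions on a genome.

    A region of length l is placed by choosing a contig with probability
    proportional to its number of placeable start positions (len - l + 1)
    and then a uniform start. Exclusion intervals are honoured by rejection
    sampling on a coverage prefix sum; GC matching (|GC - target| <= tol)
    likewise, with bounded retries.
    """

    MAX_ROUNDS = 200

    def __init__(
        self,
        genome: GenomeSequence,
        lengths: np.ndarray,
        exclusions: list[GenomicInterval] | None = None,
        gc_match: float | None = None,
        gc_targets: np.ndarray | None = None,
    ):
        self.contig_names = list(genome.contigs)
        self.clens = np.array([genome.lengths[c] for c in self.contig_names])
        self.lengths = np.asarray(lengths, dtype=np.int64)
        if (self.lengths > self.clens.max()).any():
            raise ValueError("a region length exceeds the longest contig")
        placeable = np.maximum(self.clens[None, :] - self.lengths[:, None] + 1, 0)
        totals = placeable.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("no placeable position for some region length")
        self._placeable = placeable
        self._cumprob = np.cumsum(placeable / totals[:, None], axis=1)
        self._excl_csum = self._coverage_csum(genome, exclusions) if exclusions else None
        self.gc_match = gc_match
        self.gc_targets = gc_targets
        self._gc_csum = self._gc_prefix(genome) if gc_match is not None else None
        self.gc_giveups = 0

    @staticmethod
    def _coverage_csum(genome, intervals):
        csum = {}
        for name in genome.contigs:
            cov = np.zeros(genome.lengths[name] + 1, dtype=np.int64)
            for iv in intervals:
                if iv.contig == name:
                    cov[iv.start] += 1
                    cov[min(iv.end, genome.lengths[name])] -= 1
            csum[name] = np.concatenate([[0], np.cumsum(np.cumsum(cov[:-1]) > 0)])
        return csum

    @staticmethod
    def _gc_prefix(genome):
        csum = {}
        for name, seq in genome.contigs.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            is_gc = (arr == ord("G")) | (arr == ord("C"))
            csum[name] = np.concatenate([[0], np.cumsum(is_gc)])
        return csum

    def _valid(self, cidx: np.ndarray, starts: np.ndarray, which: np.ndarray) -> np.ndarray:
        ok = np.ones(which.size, dtype=bool)
        lens = self.lengths[which]
        for ci, name in enumerate(self.contig_names):
            sel = cidx == ci
            if not sel.any():
                continue
            s, l = starts[sel], lens[sel]
            good = np.ones(s.size, dtype=bool)
            if self._excl_csum is not None:
                c = self._excl_csum[name]
                good &= (c[s + l] - c[s]) == 0
            if self._gc_csum is not None:
                c = self._gc_csum[name]
                gc = (c[s + l] - c[s]) / l
                good &= np.abs(gc - self.gc_targets[which[sel]]) <= self.gc_match
            ok[sel] = good
        return ok

    def sample(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Return (contig_index, start) arrays, one entry per region."""
        n = self.lengths.size
        which = np.arange(n)
        cidx = np.empty(n, dtype=np.int64)
        starts = np.empty(n, dtype=np.int64)
        pending = which
        for round_no in range(self.MAX_ROUNDS):
            u = rng.random(pending.size)
            ci = (u[:, None] > self._cumprob[pending]).sum(axis=1)
            s = (rng.random(pending.size) * self._placeable[pending, ci]).astype(np.int64)
            cidx[pending], starts[pending] = ci, s
            ok = self._valid(ci, s, pending)
            # GC matching is soft: on the last round accept with a warning;
            # exclusion overlap is hard and keeps rejecting.
            if round_no == self.MAX_ROUNDS - 1 and self.gc_match is not None:
                self.gc_giveups += (~ok).sum()
                break
            pending = pending[~ok]
            if pending.size == 0:
                break
        else:
            raise RuntimeError("background sampling failed to place all regions")
        if pending.size and self.gc_match is None:
            raise RuntimeError("background sampling failed to place all regions")
        return cidx, starts


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    """One independent generator per permutation from a single master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_background_regions(
    genome: GenomeSequence,
    peak_lengths: list[int],
    n_perm: int,
    seed: int = 0,
    exclusions: list[GenomicInterval] | None = None,
    gc_match: float | None = None,
    gc_targets: np.ndarray | None = None,
) -> list[NullSample]:
    """Draw ``n_perm`` random region sets length-matched to the peaks.

    Deterministic given ``seed``. With ``gc_match`` set, each region is
    resampled until its GC content is within the tolerance of the matched
    peak's (``gc_targets``); retries are bounded, and a warning is logged if
    more than 10% of regions exhaust them.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sampler = _Sampler(genome, np.asarray(peak_lengths), exclusions, gc_match, gc_targets)
    samples = []
    for rng in _child_seeds(seed, n_perm):
        cidx, starts = sampler.sample(rng)
        regions = [
            GenomicInterval(
                sampler.contig_names[c], int(s), int(s) + int(l), name=f"null_{k + 1}"
            )
            for k, (c, s, l) in enumerate(zip(cidx, starts, sampler.lengths))
        ]
        samples.append(NullSample(regions=regions))
    if sampler.gc_giveups > 0.10 * n_perm * len(peak_lengths):
        logger.warning(
            "GC matching gave up on %d regions (>10%%); tolerance may be too tight",
            sampler.gc_giveups,
        )
    return samples


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Fitted permutation-enrichment results for one motif.

    ``fold_enrichment = observed_count / null_mean`` and
    ``empirical_p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """

    tf_name: str
    observed_count: int
    n_peaks: int
    null_counts: np.ndarray
    seed: int
    null_mean: float = field(init=False)
    null_sd: float = field(init=False)
    fold_enrichment: float = field(init=False)
    empirical_p: float = field(init=False)
    z: float = field(init=False)

    def __post_init__(self) -> None:
        nc = np.asarray(self.null_counts, dtype=float)
        self.null_counts = nc
        self.null_mean = float(nc.mean())
        self.null_sd = float(nc.std(ddof=1)) if nc.size > 1 else float("nan")
        if self.null_mean > 0:
            self.fold_enrichment = self.observed_count / self.null_mean
        else:
            warnings.warn("null mean is zero; fold enrichment reported as +inf")
            self.fold_enrichment = float("inf")
        self.empirical_p = (1 + int((nc >= self.observed_count).sum())) / (1 + nc.size)
        self.z = (
            (self.observed_count - self.null_mean) / self.null_sd
            if self.null_sd and self.null_sd > 0
            else float("nan")
        )

    @property
    def n_perm(self) -> int:
        return int(self.null_counts.size)

    def to_dict(self) -> dict:
        return {
            "tf": self.tf_name,
            "n_peaks": self.n_peaks,
            "observed": self.observed_count,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "fold": self.fold_enrichment,
            "empirical_p": self.empirical_p,
            "z": self.z,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Motif enrichment (permutation test)",
            "=" * 42,
            f"{'motif':<22}{d['tf']:>20}",
            f"{'peaks scanned':<22}{d['n_peaks']:>20}",
            f"{'peaks with motif':<22}{d['observed']:>20}",
            f"{'null mean':<22}{d['null_mean']:>20.2f}",
            f"{'null sd':<22}{d['null_sd']:>20.2f}",
            f"{'fold enrichment':<22}{d['fold']:>20.3f}",
            f"{'empirical p':<22}{d['empirical_p']:>20.4g}",
            f"{'z':<22}{d['z']:>20.2f}",
            f"{'permutations':<22}{d['n_perm']:>20}",
            f"{'seed':<22}{d['seed']:>20}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class MotifEnrichmentTest:
    """Permutation enrichment of one motif in a peak set on a genome.

    Parameters
    ----------
    peaks : list of GenomicInterval
        The observed (e.g. treatment-dependent) peak set.
    genome : GenomeSequence
        Sequence universe for scanning and for placing null regions.
    pwm : PositionWeightMatrix
        Calibrated motif model.
    exclusions : list of GenomicInterval, optional
        Regions null samples must avoid (e.g. the peaks themselves).
    gc_match : float, optional
        GC tolerance; each null region is resampled until its GC content is
        within this distance of its matched peak's.
    """

    def __init__(
        self,
        peaks: list[GenomicInterval],
        genome: GenomeSequence,
        pwm: PositionWeightMatrix,
        exclusions: list[GenomicInterval] | None = None,
        gc_match: float | None = None,
    ):
        if not peaks:
            raise ValueError("peak set is empty")
        if not pwm.is_calibrated:
            raise ValueError("PWM threshold not calibrated")
        self.peaks = peaks
        self.genome = genome
        self.pwm = pwm
        self.exclusions = exclusions
        self.gc_match = gc_match

    def fit(
        self,
        n_perm: int = 1000,
        seed: int = 0,
        index: GenomeScanIndex | None = None,
    ) -> EnrichmentResult:
        """Run the permutation test and return an :class:`EnrichmentResult`."""
        if index is None:
            index = GenomeScanIndex(self.genome, self.pwm)
        flags, observed, _ = peaks_with_motif(self.peaks, self.genome, self.pwm, index=index)
        lengths = np.array([len(p) for p in self.peaks], dtype=np.int64)
        gc_targets = None
        if self.gc_match is not None:
            gc_targets = np.array(
                [_gc_of(self.genome.fetch_interval(p)) for p in self.peaks]
            )
        sampler = _Sampler(self.genome, lengths, self.exclusions, self.gc_match, gc_targets)
        null_counts = np.empty(n_perm, dtype=np.int64)
        for j, rng in enumerate(_child_seeds(seed, n_perm)):
            cidx, starts = sampler.sample(rng)
            count = 0
            for ci, name in enumerate(sampler.contig_names):
                sel = cidx == ci
                if sel.any():
                    count += int(
                        index.contains_motif_batch(
                            name, starts[sel], starts[sel] + lengths[sel]
                        ).sum()
                    )
            null_counts[j] = count
        if sampler.gc_giveups > 0.10 * n_perm * len(self.peaks):
            logger.warning("GC matching gave up on >10%% of null regions")
        return EnrichmentResult(
            tf_name=self.pwm.motif_name,
            observed_count=observed,
            n_peaks=len(self.peaks),
            null_counts=null_counts,
            seed=seed,
        )


def _gc_of(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / max(len(seq), 1)


def motif_enrichment(
    peaks: list[GenomicInterval],
    genome: GenomeSequence,
    pwm: PositionWeightMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    exclusions: list[GenomicInterval] | None = None,
    gc_match: float | None = None,
    index: GenomeScanIndex | None = None,
) -> EnrichmentResult:
    """Functional wrapper around :class:`MotifEnrichmentTest`."""
    model = MotifEnrichmentTest(peaks, genome, pwm, exclusions=exclusions, gc_match=gc_match)
    return model.fit(n_perm=n_perm, seed=seed, index=index)


def multi_tf_enrichment(
    peaks: list[GenomicInterval],
    genome: GenomeSequence,
    motifs: dict[str, PositionWeightMatrix],
    n_perm: int = 1000,
    seed: int = 0,
    exclusions: list[GenomicInterval] | None = None,
    gc_match: float | None = None,
) -> pd.DataFrame:
    """Test several motifs against the same peaks with shared null geometry.

    The random region placements are identical across motifs (same seed and
    sampler), so differences between rows reflect the motifs alone. Returns
    one row per motif, sorted by fold enrichment descending, ties broken by
    motif name.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    names = list(motifs)
    if len(set(names)) != len(names):
        raise ValueError("duplicate TF names")
    rows = []
    for name, pwm in motifs.items():
        res = motif_enrichment(
            peaks, genome, pwm, n_perm=n_perm, seed=seed,
            exclusions=exclusions, gc_match=gc_match,
        )
        row = res.to_dict()
        row["tf"] = name
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["fold", "tf"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def motif_fraction_summary(flags) -> tuple[int, int]:
    """(count, integer percent) of True flags, e.g. (847, 23) for 847/3633."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty flag vector")
    count = int(flags.sum())
    return count, int(round(100.0 * count / flags.size))
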