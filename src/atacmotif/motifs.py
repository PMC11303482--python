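"""Position-weight-matrix motif models: construction, exact threshold
calibration, and two-strand scanning.

The match definition used throughout the package: a window of length L is a
motif hit when its log2-odds score (motif vs. background base composition)
reaches a threshold calibrated so that a random background L-mer passes with
probability at most ``alpha``. The threshold is obtained by dynamic
programming over the discretised exact score distribution (per-column score
mass functions convolved across columns), not by sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import GenomeSequence, GenomicInterval

__all__ = [
    "PositionCountMatrix",
    "BackgroundModel",
    "PositionWeightMatrix",
    "MotifHit",
    "build_pwm",
    "calibrate_threshold",
    "scan_sequence",
    "peaks_with_motif",
    "GenomeScanIndex",
    "encode_sequence",
    "reverse_complement",
]

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_CODE_TO_BASE = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level lookup table: ASCII code -> base code (-1 for N / anything else)
_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _c in _BASE_TO_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an {A,C,G,T,N} string as int8 codes (A=0..T=3, N=-1)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PositionCountMatrix:
    """4 x L base counts (row order A, C, G, T) for one motif."""

    counts: np.ndarray
    motif_name: str = "motif"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x L matrix with L >= 1")
        if (counts < 0).any():
            raise ValueError("negative count in position count matrix")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError("column with zero total count")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_CODE_TO_BASE[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class BackgroundModel:
    """Independent-base background distribution (q_A, q_C, q_G, q_T)."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (4,) or (q <= 0).any() or not np.isclose(q.sum(), 1.0):
            raise ValueError("background must be 4 positive frequencies summing to 1")
        object.__setattr__(self, "q", q)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_gc(cls, gc: float) -> "BackgroundModel":
        if not 0 < gc < 1:
            raise ValueError("gc must be in (0, 1)")
        return cls(np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]))

    @classmethod
    def from_genome(cls, genome: GenomeSequence) -> "BackgroundModel":
        return cls.from_gc(genome.gc_fraction())


@dataclass
class PositionWeightMatrix:
    """Log2-odds scoring matrix with an (optionally calibrated) hit threshold.

    ``weights[b, i] = log2(f[b, i] / q_b)`` where
    ``f[b, i] = (counts[b, i] + pseudocount * q_b) / (N_i + pseudocount)``.
    ``threshold`` is None until :func:`calibrate_threshold` sets it; ``alpha``
    records the tail probability the threshold was calibrated to and
    ``attained_p`` the tail mass the discretised distribution actually
    achieves at the threshold.
    """

    weights: np.ndarray
    background: BackgroundModel
    pseudocount: float
    motif_name: str = "motif"
    threshold: float | None = None
    alpha: float | None = None
    attained_p: float | None = None
    consensus: str = ""

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def is_calibrated(self) -> bool:
        return self.threshold is not None

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    def reverse_complement_weights(self) -> np.ndarray:
        """Weights that score the forward strand as if scanning the reverse."""
        return self.weights[::-1, ::-1]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence at forward-strand window coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    score: float


def build_pwm(
    pcm: PositionCountMatrix,
    bg: BackgroundModel | None = None,
    pseudocount: float = 0.8,
) -> PositionWeightMatrix:
    """Standard log2-odds PWM from counts, pseudocount split by background.

    The threshold is left uncalibrated; pass the result through
    :func:`calibrate_threshold` before scanning.
    """
    if bg is None:
        bg = BackgroundModel.uniform()
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    col_sums = pcm.counts.sum(axis=0)
    f = (pcm.counts + pseudocount * bg.q[:, None]) / (col_sums + pseudocount)
    weights = np.log2(f / bg.q[:, None])
    return PositionWeightMatrix(
        weights=weights,
        background=bg,
        pseudocount=pseudocount,
        motif_name=pcm.motif_name,
        consensus=pcm.consensus,
    )


def calibrate_threshold(
    pwm: PositionWeightMatrix,
    alpha: float = 1e-4,
    granularity: float = 1e-3,
) -> PositionWeightMatrix:
    """Set the hit threshold so a random background L-mer passes with p <= alpha.

    The per-column score mass functions are discretised at ``granularity``
    bits and convolved into the exact (discretised) distribution of the full
    window score; the threshold is the smallest discretised score whose upper
    tail mass is <= alpha, relaxed by half a granularity step per column so a
    word on the quantisation boundary is never rejected. The attained tail
    mass is stored on the PWM. Returns the same PWM object, calibrated.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    L = pwm.length
    q = np.round(pwm.weights / granularity).astype(np.int64)  # 4 x L
    lo = int(q.min(axis=0).sum())
    hi = int(q.max(axis=0).sum())
    pmf = np.zeros(hi - lo + 1)
    pmf[0] = 1.0  # distribution of (partial sum - running lo), offset bookkeeping
    offset = 0  # partial sums live at index (value - running_lo)
    running_lo = 0
    for i in range(L):
        col = q[:, i]
        col_lo = int(col.min())
        width = int(col.max()) - col_lo
        new = np.zeros(min(offset + width + 1, hi - lo + 1))
        for b in range(4):
            shift = int(col[b]) - col_lo
            new[shift : shift + offset + 1] += pwm.background.q[b] * pmf[: offset + 1]
        pmf = np.zeros(hi - lo + 1)
        pmf[: new.size] = new
        offset += width
        running_lo += col_lo
    # survival[k] = P(quantised score >= lo + k)
    survival = pmf[::-1].cumsum()[::-1]
    passing = np.nonzero(survival <= alpha)[0]
    if passing.size:
        k = int(passing[0])
        attained = float(survival[k])
    else:  # alpha smaller than the mass of the best word: nothing passes
        k = hi - lo + 1
        attained = 0.0
    pwm.threshold = (lo + k) * granularity - L * granularity / 2.0
    pwm.alpha = alpha
    pwm.attained_p = attained
    return pwm


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scores of every length-L window; windows containing N get -inf."""
    L = weights.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    # pad with a fifth zero row so N (code -1 -> index 4) is harmless
    w = np.vstack([weights, np.zeros((1, L))])
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i in range(L):
        c = codes[i : i + n].astype(np.intp)
        valid &= c >= 0
        scores += w[np.where(c < 0, 4, c), i]
    scores[~valid] = -np.inf
    return scores


def scan_sequence(
    pwm: PositionWeightMatrix,
    sequence: str,
    contig: str = "",
    offset: int = 0,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Report every window scoring at or above the calibrated threshold.

    Minus-strand windows are scored against the reverse complement and
    reported at forward-strand coordinates. Windows containing N are
    skipped. Hits are sorted by start, "+" before "-" at equal starts.
    """
    if not pwm.is_calibrated:
        raise ValueError("PWM threshold not calibrated; call calibrate_threshold")
    codes = encode_sequence(sequence.upper())
    fwd = _window_scores(codes, pwm.weights)
    hits: list[MotifHit] = []
    L = pwm.length
    for pos in np.nonzero(fwd >= pwm.threshold)[0]:
        hits.append(MotifHit(contig, offset + int(pos), offset + int(pos) + L, "+", float(fwd[pos])))
    if both_strands:
        rev = _window_scores(codes, pwm.reverse_complement_weights())
        for pos in np.nonzero(rev >= pwm.threshold)[0]:
            hits.append(MotifHit(contig, offset + int(pos), offset + int(pos) + L, "-", float(rev[pos])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


class GenomeScanIndex:
    """Genome-wide hit index for one calibrated PWM.

    Precomputes, per contig, a prefix sum over the indicator "a hit (either
    strand) starts here", so that 'does region [s, e) contain >= 1 motif?'
    is answered in O(1). Used by the permutation machinery where millions of
    containment queries are made against a fixed genome.
    """

    def __init__(self, genome: GenomeSequence, pwm: PositionWeightMatrix):
        if not pwm.is_calibrated:
            raise ValueError("PWM threshold not calibrated")
        self.genome = genome
        self.pwm = pwm
        self.L = pwm.length
        self._csum: dict[str, np.ndarray] = {}
        rc = pwm.reverse_complement_weights()
        for name, seq in genome.contigs.items():
            codes = encode_sequence(seq)
            fwd = _window_scores(codes, pwm.weights)
            rev = _window_scores(codes, rc)
            hit = (fwd >= pwm.threshold) | (rev >= pwm.threshold)
            self._csum[name] = np.concatenate([[0], np.cumsum(hit)])

    def contains_motif(self, contig: str, start: int, end: int) -> bool:
        n_windows = end - start - self.L + 1
        if n_windows <= 0:
            return False
        c = self._csum[contig]
        return bool(c[start + n_windows] - c[start] > 0)

    def contains_motif_batch(
        self, contig: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorised containment flags for many regions on one contig."""
        c = self._csum[contig]
        last = np.maximum(starts + (ends - starts - self.L + 1), starts)
        return (c[last] - c[starts]) > 0


def peaks_with_motif(
    peaks: list[GenomicInterval],
    genome: GenomeSequence,
    pwm: PositionWeightMatrix,
    index: GenomeScanIndex | None = None,
    collect_hits: bool = False,
):
    """Flag each peak that contains >= 1 motif hit on either strand.

    Returns ``(flags, count, hits_by_peak)``; ``hits_by_peak`` maps a peak
    name to its hit list only when ``collect_hits`` is requested (the flags
    themselves come from the O(1) genome index). Raises ``ValueError`` naming
    the offending peak if one falls outside its contig.
    """
    for p in peaks:
        if p.contig not in genome:
            raise ValueError(f"peak {p.name}: unknown contig {p.contig!r}")
        if p.end > genome.lengths[p.contig]:
            raise ValueError(f"peak {p.name}: extends past end of {p.contig}")
    if index is None:
        index = GenomeScanIndex(genome, pwm)
    flags = np.array(
        [index.contains_motif(p.contig, p.start, p.end) for p in peaks], dtype=bool
    )
    hits_by_peak: dict[str, list[MotifHit]] = {}
    if collect_hits:
        for p, flagged in zip(peaks, flags):
            if flagged:
                hits_by_peak[p.name] = scan_sequence(
                    pwm, genome.fetch_interval(p), contig=p.contig, offset=p.start
                )
    return flags, int(flags.sum()), hits_by_peak
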