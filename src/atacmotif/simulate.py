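"""Synthetic genomes, peaks, gene models and differential tables with known
ground truth.

Every generator is a pure function of its parameters and a seed, and each
records what it planted in a :class:`SyntheticTruth` manifest so downstream
recovery can be checked against the truth rather than against itself. The
centrepiece is :func:`plant_motifs`, which calibrates the background motif
containment rate empirically and then overwrites consensus words into a
random subset of peaks until a chosen containment fold over background is
reached, and :func:`generate_figure2h_fixture`, a fully deterministic bundle
whose scan/filter/integration counts are exact by construction (3633
differential peaks, 847 motif-bearing, 95 upregulated genes with a <=5 kb
promoter-proximal peak, 16 of those motif-bearing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import _Sampler
from .motifs import (
    BackgroundModel,
    GenomeScanIndex,
    PositionCountMatrix,
    PositionWeightMatrix,
    build_pwm,
    calibrate_threshold,
    reverse_complement,
    scan_sequence,
)
from .types import GeneModel, GenomeSequence, GenomicInterval

__all__ = [
    "SyntheticTruth",
    "generate_genome",
    "generate_gene_models",
    "generate_peaks",
    "plant_motifs",
    "generate_differential_tables",
    "generate_figure2h_fixture",
    "Figure2HBundle",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticTruth:
    """Ground-truth manifest of what a generator planted."""

    seed: int
    genome_params: dict = field(default_factory=dict)
    planted_motif_positions: list = field(default_factory=list)  # (contig, start, strand, peak)
    planted_fold: float | None = None
    background_containment: float | None = None
    realized_containment: float | None = None
    de_labels: dict = field(default_factory=dict)
    gene_peak_truth: dict = field(default_factory=dict)
    motif_bearing_genes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genome_params": self.genome_params,
            "planted_motif_positions": [list(t) for t in self.planted_motif_positions],
            "planted_fold": self.planted_fold,
            "background_containment": self.background_containment,
            "realized_containment": self.realized_containment,
            "de_labels": self.de_labels,
            "gene_peak_truth": self.gene_peak_truth,
            "motif_bearing_genes": self.motif_bearing_genes,
        }


# ---------------------------------------------------------------------------
# Genome / genes / peaks
# ---------------------------------------------------------------------------

def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = np.searchsorted(np.cumsum(probs), rng.random(n), side="right")
    return _BASES[codes]


def generate_genome(
    n_contigs: int = 1,
    lengths: list[int] | int = 1_000_000,
    gc: float = 0.41,
    seed: int = 0,
) -> GenomeSequence:
    """I.i.d. random genome with the requested GC fraction (G and C equal)."""
    if isinstance(lengths, int):
        lengths = [lengths] * n_contigs
    if len(lengths) != n_contigs or any(l <= 0 for l in lengths):
        raise ValueError("need one positive length per contig")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    contigs = {
        f"chr{i + 1}": _random_bases(l, gc, rng).tobytes().decode("ascii")
        for i, l in enumerate(lengths)
    }
    return GenomeSequence(contigs)


def generate_gene_models(
    genome: GenomeSequence,
    n_genes: int,
    min_spacing: int = 2000,
    seed: int = 0,
) -> list[GeneModel]:
    """Place TSSs uniformly subject to a minimum pairwise spacing.

    Strands are fair coin flips; output is sorted by (contig, position).
    """
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        return []
    total = genome.total_length
    if n_genes * min_spacing > total:
        raise ValueError("spacing infeasible for this genome")
    names = list(genome.contigs)
    clens = np.array([genome.lengths[c] for c in names])
    genes: list[GeneModel] = []
    placed: dict[str, list[int]] = {c: [] for c in names}
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 200 * n_genes:
            raise ValueError("could not place genes at the requested spacing")
        ci = rng.choice(len(names), p=clens / clens.sum())
        pos = int(rng.integers(0, clens[ci]))
        if any(abs(pos - q) < min_spacing for q in placed[names[ci]]):
            continue
        placed[names[ci]].append(pos)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene_{len(genes) + 1:05d}", names[ci], strand, pos))
    genes.sort(key=lambda g: (g.contig, g.tss))
    # re-id in positional order so ids are stable and sorted
    return [
        GeneModel(f"gene_{i + 1:05d}", g.contig, g.strand, g.tss)
        for i, g in enumerate(genes)
    ]


def generate_peaks(
    genome: GenomeSequence,
    n_peaks: int,
    length_mean: float = 400.0,
    length_sd: float = 80.0,
    seed: int = 0,
    non_overlapping: bool = False,
    min_length: int = 50,
) -> list[GenomicInterval]:
    """Random peaks with truncated-normal lengths (>= ``min_length``)."""
    rng = np.random.default_rng(seed)
    a = (min_length - length_mean) / length_sd
    lengths = stats.truncnorm.rvs(
        a, np.inf, loc=length_mean, scale=length_sd, size=n_peaks, random_state=rng
    ).round().astype(np.int64)
    names = list(genome.contigs)
    clens = np.array([genome.lengths[c] for c in names])
    peaks: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    for k, l in enumerate(lengths):
        for attempt in range(1000):
            placeable = np.maximum(clens - l + 1, 0)
            if placeable.sum() == 0:
                raise ValueError(f"peak length {l} exceeds all contigs")
            ci = rng.choice(len(names), p=placeable / placeable.sum())
            s = int(rng.integers(0, placeable[ci]))
            if non_overlapping and any(
                s < e0 and s + l > s0 for s0, e0 in occupied[names[ci]]
            ):
                continue
            occupied[names[ci]].append((s, s + int(l)))
            peaks.append(
                GenomicInterval(names[ci], s, s + int(l), name=f"peak_{k + 1}")
            )
            break
        else:
            raise ValueError("could not pack non-overlapping peaks")
    return peaks


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def _mutate(contigs: dict[str, bytearray], contig: str, start: int, word: str) -> None:
    contigs[contig][start : start + len(word)] = word.encode("ascii")


def plant_motifs(
    genome: GenomeSequence,
    peaks: list[GenomicInterval],
    pwm: PositionWeightMatrix,
    target_fold: float,
    seed: int = 0,
    calibration_n: int = 5000,
) -> tuple[GenomeSequence, SyntheticTruth]:
    """Overwrite consensus words into peaks until motif containment reaches
    ``target_fold`` times the empirical background rate.

    The background containment p0 is measured by scanning ``calibration_n``
    random length-matched regions of the unplanted genome; the target
    containment is ``min(1, target_fold * p0)``. A uniform random subset of
    currently motif-free peaks then receives the PWM consensus (random
    offset, random strand) until the target count is met. Bases outside the
    chosen peaks are never touched. ``target_fold == 1`` plants nothing.
    """
    if target_fold < 1:
        raise ValueError("target_fold must be >= 1")
    L = pwm.length
    if peaks and L > min(len(p) for p in peaks):
        raise ValueError("motif longer than the shortest peak")
    rng = np.random.default_rng(seed)
    index = GenomeScanIndex(genome, pwm)
    lengths = np.array([len(p) for p in peaks], dtype=np.int64)
    cal_lengths = rng.choice(lengths, size=calibration_n, replace=True)
    sampler = _Sampler(genome, cal_lengths)
    cidx, starts = sampler.sample(rng)
    contained = np.zeros(calibration_n, dtype=bool)
    for ci, name in enumerate(sampler.contig_names):
        sel = cidx == ci
        if sel.any():
            contained[sel] = index.contains_motif_batch(
                name, starts[sel], starts[sel] + cal_lengths[sel]
            )
    p0 = float(contained.mean())
    truth = SyntheticTruth(
        seed=seed,
        planted_fold=target_fold,
        background_containment=p0,
    )
    flags = np.array([index.contains_motif(p.contig, p.start, p.end) for p in peaks])
    if target_fold == 1.0:
        truth.realized_containment = float(flags.mean()) if peaks else 0.0
        return genome, truth
    target_c = target_fold * p0
    if target_c > 1:
        raise ValueError("saturated planting: target_fold * p0 > 1")
    n_target = int(round(target_c * len(peaks)))
    n_plant = n_target - int(flags.sum())
    if n_plant <= 0:
        truth.realized_containment = float(flags.mean())
        return genome, truth
    free = np.nonzero(~flags)[0]
    if n_plant > free.size:
        raise ValueError("not enough motif-free peaks to reach the target fold")
    consensus = pwm.consensus
    if not scan_sequence(pwm, consensus):
        raise ValueError("consensus word does not pass the calibrated threshold")
    contigs = {n: bytearray(s, "ascii") for n, s in genome.contigs.items()}
    # peaks may overlap, so one planted word can flip several peaks at once;
    # plant incrementally and propagate flags to every peak containing the word
    by_contig: dict[str, np.ndarray] = {}
    for ci, p in enumerate(peaks):
        by_contig.setdefault(p.contig, []).append(ci)
    for contig, idxs in by_contig.items():
        idxs = np.array(sorted(idxs, key=lambda i: peaks[i].start))
        by_contig[contig] = idxs
    max_len = max(len(p) for p in peaks)
    count = int(flags.sum())
    for pi in rng.permutation(free):
        if count >= n_target:
            break
        if flags[pi]:
            continue  # flipped as a side effect of an earlier plant
        p = peaks[pi]
        start = int(rng.integers(p.start, p.end - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        word = consensus if strand == "+" else reverse_complement(consensus)
        _mutate(contigs, p.contig, start, word)
        truth.planted_motif_positions.append((p.contig, start, strand, p.name))
        idxs = by_contig[p.contig]
        starts_sorted = np.array([peaks[i].start for i in idxs])
        lo = int(np.searchsorted(starts_sorted, start - max_len, side="left"))
        hi = int(np.searchsorted(starts_sorted, start, side="right"))
        for j in idxs[lo:hi]:
            if not flags[j] and peaks[j].start <= start and peaks[j].end >= start + L:
                flags[j] = True
                count += 1
    if count < n_target:
        raise ValueError("not enough motif-free peaks to reach the target fold")
    mutated = GenomeSequence({n: bytes(b).decode("ascii") for n, b in contigs.items()})
    new_index = GenomeScanIndex(mutated, pwm)
    new_flags = np.array(
        [new_index.contains_motif(p.contig, p.start, p.end) for p in peaks]
    )
    truth.realized_containment = float(new_flags.mean())
    return mutated, truth


# ---------------------------------------------------------------------------
# Differential tables
# ---------------------------------------------------------------------------

def generate_differential_tables(
    n_genes: int,
    n_up: int,
    n_down: int,
    effect_size_lfc: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Gene differential table with planted up/down/null labels.

    Up genes draw ``log2fc ~ +|N(effect, 0.5)|`` with adjusted p below 0.05;
    down genes mirror the sign; null genes get near-zero effects and
    non-significant adjusted p. Returns (table, label map).
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down exceeds n_genes")
    rng = np.random.default_rng(seed)
    ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    labels = (["up"] * n_up) + (["down"] * n_down) + (["null"] * (n_genes - n_up - n_down))
    lfc = np.empty(n_genes)
    fdr = np.empty(n_genes)
    lfc[:n_up] = np.abs(rng.normal(effect_size_lfc, 0.5, n_up))
    fdr[:n_up] = rng.uniform(0.0, 0.049, n_up)
    lfc[n_up : n_up + n_down] = -np.abs(rng.normal(effect_size_lfc, 0.5, n_down))
    fdr[n_up : n_up + n_down] = rng.uniform(0.0, 0.049, n_down)
    n_null = n_genes - n_up - n_down
    lfc[n_up + n_down :] = rng.normal(0.0, 0.2, n_null)
    fdr[n_up + n_down :] = rng.uniform(0.05, 1.0, n_null)
    table = pd.DataFrame(
        {
            "id": ids,
            "log2fc": lfc,
            "pvalue": fdr * rng.uniform(0.1, 1.0, n_genes),
            "fdr": fdr,
        }
    )
    return table, dict(zip(ids, labels))


# ---------------------------------------------------------------------------
# The deterministic headline-count fixture
# ---------------------------------------------------------------------------

@dataclass
class Figure2HBundle:
    """Complete deterministic input bundle with exact known counts."""

    genome: GenomeSequence
    peak_table: pd.DataFrame  # id, contig, start, end, log2fc, pvalue, fdr
    gene_models: list[GeneModel]
    gene_table: pd.DataFrame
    pcm: PositionCountMatrix
    pwm: PositionWeightMatrix
    truth: SyntheticTruth

    @property
    def up_peaks(self) -> list[GenomicInterval]:
        up = self.peak_table[self.peak_table["log2fc"] > 0]
        up = up[up["fdr"] <= 0.05]
        return [
            GenomicInterval(r.contig, int(r.start), int(r.end), name=r.id)
            for r in up.itertuples(index=False)
        ]

    @property
    def up_gene_ids(self) -> list[str]:
        return [g for g, lab in self.truth.de_labels.items() if lab == "up"]


def _scrub_spontaneous_hits(
    contigs: dict[str, bytearray],
    regions: list[GenomicInterval],
    pwm: PositionWeightMatrix,
    gc: float,
    rng: np.random.Generator,
    max_rounds: int = 60,
) -> None:
    """Rewrite any window scoring as a hit inside the given regions until none
    remain, drawing replacement bases from the background composition."""
    for region in regions:
        buf = contigs[region.contig]
        for _ in range(max_rounds):
            seq = buf[region.start : region.end].decode("ascii")
            hits = scan_sequence(pwm, seq)
            if not hits:
                break
            for h in hits:
                repl = _random_bases(h.end - h.start, gc, rng)
                buf[region.start + h.start : region.start + h.end] = repl.tobytes()
        else:
            raise RuntimeError(f"could not scrub motif hits from {region.name}")


def generate_figure2h_fixture(seed: int = 42) -> Figure2HBundle:
    """Deterministic bundle reproducing the headline integration counts.

    By construction: 3633 treatment-up differential peaks (plus 30
    control-up regions and 150 non-significant records), of which exactly
    847 (23%) carry a planted consensus; 2554 genes labelled upregulated
    (with 3128 down and 1000 null); exactly 95 upregulated genes have a peak
    edge within 5 kb of their TSS, and exactly 16 of those genes own a
    motif-bearing proximal peak. Counts are exact for every seed; the seed
    varies only the random sequence content and planting offsets.
    """
    n_prox, n_motif_prox = 95, 16
    n_up_genes, n_down_genes, n_null_genes = 2554, 3128, 1000
    n_far, n_motif_far = 3538, 831
    n_down_peaks, n_nonsig_peaks = 30, 150
    peak_len, gc = 400, 0.41
    rng = np.random.default_rng(seed)

    # --- deterministic layout on one contig -------------------------------
    a0, block = 10_000, 12_000
    prox_tss = [a0 + i * block + 1000 for i in range(n_prox)]
    prox_peaks = [(t + 3000, t + 3000 + peak_len) for t in prox_tss]
    b0 = a0 + n_prox * block + 20_000
    n_b_genes = (n_up_genes - n_prox) + n_down_genes + n_null_genes
    b_tss = [b0 + k * 500 for k in range(n_b_genes)]
    c0 = b0 + n_b_genes * 500 + 20_000
    far_spans = [(c0 + k * 600, c0 + k * 600 + peak_len) for k in range(n_far)]
    d0 = c0 + n_far * 600
    down_spans = [(d0 + k * 600, d0 + k * 600 + peak_len) for k in range(n_down_peaks)]
    e0 = d0 + n_down_peaks * 600
    ns_spans = [(e0 + k * 600, e0 + k * 600 + peak_len) for k in range(n_nonsig_peaks)]
    genome_len = e0 + n_nonsig_peaks * 600 + 10_000

    contig = "chr1"
    contigs = {contig: bytearray(_random_bases(genome_len, gc, rng).tobytes())}

    # --- motif model -------------------------------------------------------
    pcm = sox9_synthetic_pcm()
    pwm = calibrate_threshold(build_pwm(pcm, BackgroundModel.from_gc(gc)), alpha=1e-4)

    # --- gene models and labels -------------------------------------------
    genes: list[GeneModel] = []
    labels: dict[str, str] = {}
    for i, t in enumerate(prox_tss):
        gid = f"gene_up_{i + 1:04d}"
        genes.append(GeneModel(gid, contig, "+" if i % 2 == 0 else "-", t))
        labels[gid] = "up"
    cursor = n_prox
    for k, t in enumerate(b_tss):
        if cursor < n_up_genes:
            gid, lab = f"gene_up_{cursor + 1:04d}", "up"
            cursor += 1
        elif k < (n_up_genes - n_prox) + n_down_genes:
            gid, lab = f"gene_dn_{k - (n_up_genes - n_prox) + 1:04d}", "down"
        else:
            gid, lab = f"gene_nl_{k - (n_up_genes - n_prox) - n_down_genes + 1:04d}", "null"
        genes.append(GeneModel(gid, contig, "+" if k % 2 == 0 else "-", t))
        labels[gid] = lab

    # --- peak intervals ----------------------------------------------------
    def ivs(spans, prefix):
        return [
            GenomicInterval(contig, s, e, name=f"{prefix}_{i + 1:04d}")
            for i, (s, e) in enumerate(spans)
        ]

    prox_ivs = ivs(prox_peaks, "peak_prox")
    far_ivs = ivs(far_spans, "peak_far")
    down_ivs = ivs(down_spans, "peak_veh")
    ns_ivs = ivs(ns_spans, "peak_ns")
    up_ivs = prox_ivs + far_ivs

    # --- scrub spontaneous hits, then plant -------------------------------
    _scrub_spontaneous_hits(contigs, up_ivs, pwm, gc, rng)
    consensus = pwm.consensus
    truth = SyntheticTruth(
        seed=seed,
        genome_params={"contigs": 1, "length": genome_len, "gc": gc},
        de_labels=labels,
    )
    planted = prox_ivs[:n_motif_prox] + far_ivs[:n_motif_far]
    for p in planted:
        start = int(rng.integers(p.start, p.end - pwm.length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        word = consensus if strand == "+" else reverse_complement(consensus)
        _mutate(contigs, p.contig, start, word)
        truth.planted_motif_positions.append((p.contig, start, strand, p.name))
    truth.motif_bearing_genes = [f"gene_up_{i + 1:04d}" for i in range(n_motif_prox)]
    truth.gene_peak_truth = {
        f"gene_up_{i + 1:04d}": [prox_ivs[i].name] for i in range(n_prox)
    }

    genome = GenomeSequence({contig: bytes(contigs[contig]).decode("ascii")})

    # --- differential tables ----------------------------------------------
    def peak_rows(intervals, lfc_lo, lfc_hi, fdr_lo, fdr_hi):
        n = len(intervals)
        return pd.DataFrame(
            {
                "id": [p.name for p in intervals],
                "contig": [p.contig for p in intervals],
                "start": [p.start for p in intervals],
                "end": [p.end for p in intervals],
                "log2fc": rng.uniform(lfc_lo, lfc_hi, n),
                "fdr": rng.uniform(fdr_lo, fdr_hi, n),
            }
        )

    peak_table = pd.concat(
        [
            peak_rows(up_ivs, 1.2, 4.0, 0.001, 0.049),
            peak_rows(down_ivs, -3.0, -1.2, 0.001, 0.049),
            peak_rows(ns_ivs, -0.9, 0.9, 0.06, 0.95),
        ],
        ignore_index=True,
    )
    peak_table["pvalue"] = peak_table["fdr"] * rng.uniform(0.1, 1.0, len(peak_table))
    peak_table = peak_table[["id", "contig", "start", "end", "log2fc", "pvalue", "fdr"]]

    order = {"up": 0, "down": 1, "null": 2}
    by_label = sorted(labels, key=lambda g: (order[labels[g]], g))
    lfc = np.empty(len(by_label))
    fdr = np.empty(len(by_label))
    lfc[:n_up_genes] = np.abs(rng.normal(2.0, 0.5, n_up_genes))
    fdr[:n_up_genes] = rng.uniform(0.001, 0.049, n_up_genes)
    lfc[n_up_genes : n_up_genes + n_down_genes] = -np.abs(rng.normal(2.0, 0.5, n_down_genes))
    fdr[n_up_genes : n_up_genes + n_down_genes] = rng.uniform(0.001, 0.049, n_down_genes)
    lfc[n_up_genes + n_down_genes :] = rng.normal(0.0, 0.2, n_null_genes)
    fdr[n_up_genes + n_down_genes :] = rng.uniform(0.05, 1.0, n_null_genes)
    gene_table = pd.DataFrame(
        {
            "id": by_label,
            "log2fc": lfc,
            "pvalue": fdr * rng.uniform(0.1, 1.0, len(by_label)),
            "fdr": fdr,
        }
    )

    bundle = Figure2HBundle(
        genome=genome,
        peak_table=peak_table,
        gene_models=genes,
        gene_table=gene_table,
        pcm=pcm,
        pwm=pwm,
        truth=truth,
    )
    _validate_figure2h(bundle, n_motif_prox + n_motif_far, n_prox, n_motif_prox)
    return bundle


def _validate_figure2h(bundle: Figure2HBundle, n_motif: int, n_prox: int, n_motif_prox: int) -> None:
    """Re-derive the promised counts from the generated data (fail loudly)."""
    from .integration import assign_peaks_to_promoters, candidate_direct_targets
    from .motifs import peaks_with_motif

    peaks = bundle.up_peaks
    flags, count, _ = peaks_with_motif(peaks, bundle.genome, bundle.pwm)
    if count != n_motif:
        raise RuntimeError(f"fixture self-check: motif peaks {count} != {n_motif}")
    mapping = assign_peaks_to_promoters(peaks, bundle.gene_models, max_dist=5000)
    flag_map = {p.name: bool(f) for p, f in zip(peaks, flags)}
    res = candidate_direct_targets(bundle.up_gene_ids, mapping, flag_map)
    if (res.n_with_proximal_peak, res.n_with_motif_peak) != (n_prox, n_motif_prox):
        raise RuntimeError(
            "fixture self-check: integration counts "
            f"({res.n_with_proximal_peak}, {res.n_with_motif_peak}) != ({n_prox}, {n_motif_prox})"
        )


def sox9_synthetic_pcm() -> PositionCountMatrix:
    """A synthetic SOX9-like count matrix (AACAAT-core HMG-box consensus).

    Not a database matrix: counts are invented to give a sharply defined
    9 bp motif suitable for planting and recovery experiments.
    """
    consensus = "AACAATGGC"
    return _pcm_from_consensus(consensus, "SOX9_synthetic", dominant=85, minor=5)


def _pcm_from_consensus(
    consensus: str, name: str, dominant: int = 85, minor: int = 5
) -> PositionCountMatrix:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.full((4, len(consensus)), minor, dtype=float)
    for i, base in enumerate(consensus):
        counts[idx[base], i] = dominant
    return PositionCountMatrix(counts, motif_name=name)
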