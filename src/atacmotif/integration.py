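"""TSS-centred accessibility profiles and promoter-window peak-gene
integration.

Two questions are answered here. First, how is peak coverage distributed
around transcription start sites (a metaprofile over TSS +/- window)?
Second, which upregulated genes have a treatment-dependent peak near their
promoter (within ``max_dist`` of the TSS), and which of those peaks contain
a motif — the chain that nominates candidate direct targets of the motif's
transcription factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "TssProfile",
    "IntegrationResult",
    "tss_metaprofile",
    "assign_peaks_to_promoters",
    "candidate_direct_targets",
]


# ---------------------------------------------------------------------------
# TSS metaprofile
# ---------------------------------------------------------------------------

@dataclass
class TssProfile:
    """Per-gene fraction-of-bin-covered matrix around TSSs, plus its mean.

    ``matrix`` is genes x bins in [0, 1] (NaN where a bin fell outside the
    contig); bins tile [tss - window, tss + window) left to right in the
    gene's 5'->3' orientation. ``column_means`` is the per-bin mean over
    genes, ignoring NaN.
    """

    window: int
    n_bins: int
    gene_ids: list[str]
    matrix: np.ndarray
    column_means: np.ndarray = None

    def __post_init__(self) -> None:
        if self.column_means is None:
            if self.matrix.size:
                import warnings

                with warnings.catch_warnings():
                    # a bin that is out of range for every gene is all-NaN
                    warnings.simplefilter("ignore", RuntimeWarning)
                    self.column_means = np.nanmean(self.matrix, axis=0)
            else:
                self.column_means = np.zeros(self.n_bins)


class _CoverageIndex:
    """Merged-interval coverage with O(log n) covered-bases range queries."""

    def __init__(self, intervals: list[GenomicInterval]):
        self.by_contig: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
        for contig, spans in per_contig.items():
            spans.sort()
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            cumlen = np.concatenate([[0], np.cumsum(ends - starts)])
            self.by_contig[contig] = (starts, ends, cumlen)

    def covered_bases(self, contig: str, a: int, b: int) -> int:
        """Number of covered positions in [a, b)."""
        if contig not in self.by_contig or b <= a:
            return 0
        starts, ends, cumlen = self.by_contig[contig]
        i = int(np.searchsorted(ends, a, side="right"))
        j = int(np.searchsorted(starts, b, side="left"))
        if i >= j:
            return 0
        total = int(cumlen[j] - cumlen[i])
        total -= max(0, a - starts[i])
        total -= max(0, ends[j - 1] - b)
        return total


def tss_metaprofile(
    peaks: list[GenomicInterval],
    gene_models: list[GeneModel],
    contig_lengths: dict[str, int],
    window: int = 1000,
    n_bins: int = 100,
) -> TssProfile:
    """Fraction of each bin around every TSS covered by the peak union.

    Bins tile [tss - window, tss + window); minus-strand genes have their
    profile reversed so the bin axis always runs 5' to 3'. Bins extending
    past a contig edge are NaN and excluded from the aggregate mean.
    """
    if 2 * window % n_bins != 0:
        logger.warning("2*window (%d) not a multiple of n_bins (%d); bins use integer edges", 2 * window, n_bins)
    cov = _CoverageIndex(peaks)
    edges = np.linspace(-window, window, n_bins + 1).astype(np.int64)
    matrix = np.full((len(gene_models), n_bins), np.nan)
    for gi, gene in enumerate(gene_models):
        clen = contig_lengths.get(gene.contig)
        if clen is None:
            raise ValueError(f"gene {gene.gene_id}: contig {gene.contig!r} not in universe")
        for bi in range(n_bins):
            a, b = gene.tss + edges[bi], gene.tss + edges[bi + 1]
            if a < 0 or b > clen:
                continue  # out-of-range bin stays NaN
            matrix[gi, bi] = cov.covered_bases(gene.contig, int(a), int(b)) / (b - a)
        if gene.strand == "-":
            matrix[gi] = matrix[gi, ::-1]
    return TssProfile(
        window=window,
        n_bins=n_bins,
        gene_ids=[g.gene_id for g in gene_models],
        matrix=matrix,
    )


# ---------------------------------------------------------------------------
# Promoter assignment and target nomination
# ---------------------------------------------------------------------------

def peak_tss_distance(peak: GenomicInterval, tss: int) -> int:
    """Distance from a peak to a TSS point: 0 if the TSS lies inside the
    peak, otherwise the distance from the nearest contained base."""
    if peak.start <= tss < peak.end:
        return 0
    return min(abs(tss - peak.start), abs(tss - (peak.end - 1)))


def assign_peaks_to_promoters(
    peaks: list[GenomicInterval],
    gene_models: list[GeneModel],
    max_dist: int = 5000,
    anchor: str = "edge",
) -> dict[str, list[str]]:
    """Map each gene to the peaks within ``max_dist`` of its TSS.

    ``anchor="edge"`` (default) measures from the nearest peak edge (zero if
    the TSS lies inside the peak); ``anchor="center"`` measures from the
    peak midpoint. The boundary is inclusive: distance exactly ``max_dist``
    assigns. A peak may map to several genes and a gene may hold several
    peaks; genes with no nearby peak map to an empty list.
    """
    if anchor not in ("edge", "center"):
        raise ValueError(f"unknown anchor {anchor!r}")
    peaks_by_contig: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        peaks_by_contig.setdefault(p.contig, []).append(p)
    # sort peaks by start and sweep with searchsorted windows per gene
    sorted_peaks: dict[str, tuple[np.ndarray, list[GenomicInterval]]] = {}
    for contig, plist in peaks_by_contig.items():
        plist.sort(key=lambda p: p.start)
        sorted_peaks[contig] = (np.array([p.start for p in plist]), plist)
    gene_contigs = {g.contig for g in gene_models}
    if gene_models and peaks and not gene_contigs & set(peaks_by_contig):
        raise ValueError("gene models and peaks share no contig names")
    max_len = max((len(p) for p in peaks), default=0)
    mapping: dict[str, list[str]] = {}
    for gene in gene_models:
        hits: list[str] = []
        if gene.contig in sorted_peaks:
            starts, plist = sorted_peaks[gene.contig]
            lo = int(np.searchsorted(starts, gene.tss - max_dist - max_len, side="left"))
            hi = int(np.searchsorted(starts, gene.tss + max_dist + 1, side="right"))
            for p in plist[lo:hi]:
                if anchor == "edge":
                    d = peak_tss_distance(p, gene.tss)
                else:
                    d = abs(gene.tss - (p.start + p.end) // 2)
                if d <= max_dist:
                    hits.append(p.name)
        mapping[gene.gene_id] = hits
    return mapping


@dataclass
class IntegrationResult:
    """Counts and gene lists for the promoter-integration chain."""

    n_up_genes: int
    genes_with_proximal_peak: list[str]
    genes_with_motif_peak: list[str]
    window_bp: int

    def __post_init__(self) -> None:
        assert set(self.genes_with_motif_peak) <= set(self.genes_with_proximal_peak), (
            "motif-peak genes must be a subset of proximal-peak genes"
        )

    @property
    def n_with_proximal_peak(self) -> int:
        return len(self.genes_with_proximal_peak)

    @property
    def n_with_motif_peak(self) -> int:
        return len(self.genes_with_motif_peak)

    def to_dict(self) -> dict:
        return {
            "n_up_genes": self.n_up_genes,
            "n_with_proximal_peak": self.n_with_proximal_peak,
            "n_with_motif_peak": self.n_with_motif_peak,
            "window_bp": self.window_bp,
            "genes_with_proximal_peak": self.genes_with_proximal_peak,
            "genes_with_motif_peak": self.genes_with_motif_peak,
        }

    def summary(self) -> str:
        return (
            f"upregulated genes                  {self.n_up_genes}\n"
            f"... with peak within {self.window_bp} bp        {self.n_with_proximal_peak}\n"
            f"... whose peak carries a motif     {self.n_with_motif_peak}"
        )


def candidate_direct_targets(
    up_gene_ids: list[str],
    gene_peak_map: dict[str, list[str]],
    peak_motif_flags: dict[str, bool],
    window_bp: int = 5000,
) -> IntegrationResult:
    """Nominate upregulated genes whose promoter-proximal peak carries a motif.

    ``gene_peak_map`` comes from :func:`assign_peaks_to_promoters`;
    ``peak_motif_flags`` must cover every peak named in the map. Upregulated
    genes absent from the map (unannotated) count as having no peak and are
    reported once in a warning.
    """
    all_mapped = {name for peaks in gene_peak_map.values() for name in peaks}
    uncovered = all_mapped - set(peak_motif_flags)
    if uncovered:
        raise ValueError(f"{len(uncovered)} peak(s) in the map lack motif flags")
    missing = [g for g in up_gene_ids if g not in gene_peak_map]
    if missing:
        logger.warning("%d upregulated gene(s) absent from annotation; counted as peakless", len(missing))
    proximal = sorted(g for g in up_gene_ids if gene_peak_map.get(g))
    with_motif = sorted(
        g for g in proximal if any(peak_motif_flags[p] for p in gene_peak_map[g])
    )
    return IntegrationResult(
        n_up_genes=len(up_gene_ids),
        genes_with_proximal_peak=proximal,
        genes_with_motif_peak=with_motif,
        window_bp=window_bp,
    )
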