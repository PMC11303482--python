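"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; GTF input
(1-based inclusive) is converted on read and back on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class FormatError(ValueError):
    """A file violated the syntax or semantics of its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named contig."""

    contig: str
    start: int
    end: int
    name: str = ""
    strand: str = "."
    score: str = "0"  # passed through verbatim for BED6 round-trips

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its canonical transcription start site.

    ``tss`` is a 0-based genomic position: for a "+" gene the first
    transcribed base, for a "-" gene the last base of the transcript span.
    """

    gene_id: str
    contig: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


@dataclass(frozen=True)
class DifferentialRecord:
    """One row of a differential peak/gene table (effect size + significance)."""

    id: str
    log2fc: float
    pvalue: float
    fdr: float

    def __post_init__(self) -> None:
        for label, v in (("pvalue", self.pvalue), ("fdr", self.fdr)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"record {self.id}: {label}={v} outside [0, 1]")


class GenomeSequence:
    """Named contigs over the {A,C,G,T,N} alphabet.

    Sequences are stored uppercase. Acts as the substrate for motif
    scanning, background sampling and synthetic mutation.
    """

    _ALPHABET = frozenset("ACGTN")

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise FormatError("genome has no contigs")
        clean: dict[str, str] = {}
        for name, seq in contigs.items():
            if not name:
                raise FormatError("empty contig name")
            seq = seq.upper()
            bad = set(seq) - self._ALPHABET
            if bad:
                raise FormatError(
                    f"contig {name}: characters outside A/C/G/T/N: {sorted(bad)}"
                )
            clean[name] = seq
        self.contigs: dict[str, str] = clean
        self.lengths: dict[str, int] = {n: len(s) for n, s in clean.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Extract [start, end) from a contig, bounds-checked."""
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        if start < 0 or end > self.lengths[contig] or start >= end:
            raise ValueError(
                f"range {contig}:{start}-{end} outside contig of length "
                f"{self.lengths[contig]}"
            )
        return self.contigs[contig][start:end]

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.contig, iv.start, iv.end)

    def gc_fraction(self) -> float:
        gc = at = 0
        for seq in self.contigs.values():
            gc += seq.count("G") + seq.count("C")
            at += seq.count("A") + seq.count("T")
        return gc / (gc + at) if gc + at else 0.0
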