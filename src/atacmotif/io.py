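"""Readers and writers for the standard flat-file formats the pipeline touches.

FASTA (genome), BED3/BED6 (peaks and background regions), GTF (gene models),
JASPAR-style PFM text (motif count matrices) and TSV differential tables.
Everything is converted to the package's 0-based half-open convention on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import FormatError, GeneModel, GenomeSequence, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_tss_from_gtf",
    "write_gtf",
    "read_pfm",
    "write_pfm",
    "read_differential_table",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence` (uppercased).

    Raises :class:`FormatError` on an empty file, duplicate contig names, or
    characters outside {A,C,G,T,N} after uppercasing.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"{path}: duplicate contig name {record.id!r}")
        contigs[record.id] = str(record.seq)
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (0-based half-open, as BED already is).

    Unnamed intervals receive auto-generated names ``peak_<k>`` (1-based, in
    file order); a missing strand column becomes ``"."``.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else f"peak_{len(intervals) + 1}"
            score = fields[4] if len(fields) > 4 else "0"
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(
                GenomicInterval(contig, start, end, name=name, strand=strand, score=score)
            )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6. Round-trips BED6 input byte-identically."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_COLUMNS = [
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
]


def _gtf_attr(attribute: str, key: str) -> str | None:
    # attributes look like: gene_id "X"; transcript_id "Y";
    for part in attribute.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key) :].strip().strip('"')
    return None


def read_tss_from_gtf(
    path: str | Path, canonical_rule: str = "five_prime_most"
) -> list[GeneModel]:
    """Extract one canonical TSS per gene from GTF transcript features.

    GTF coordinates are 1-based inclusive; the returned TSS is 0-based:
    ``start - 1`` for "+" transcripts and ``end - 1`` for "-" transcripts.
    Multiple transcripts per gene are resolved by ``canonical_rule``:
    ``five_prime_most`` (default) takes the most 5' TSS on the gene's strand,
    ``first_transcript`` the first transcript in file order. Genes that appear
    only as ``gene`` features with no transcript are skipped with a warning.
    """
    if canonical_rule not in ("five_prime_most", "first_transcript"):
        raise ValueError(f"unknown canonical_rule {canonical_rule!r}")
    df = pd.read_csv(
        str(path), sep="\t", comment="#", header=None, names=_GTF_COLUMNS,
        dtype={"seqname": str, "feature": str, "strand": str},
    )
    genes: dict[str, GeneModel] = {}
    seen_gene_features: set[str] = set()
    for row in df.itertuples(index=False):
        gene_id = _gtf_attr(row.attribute, "gene_id")
        if gene_id is None:
            raise FormatError(f"{path}: record without gene_id attribute")
        if row.feature == "gene":
            seen_gene_features.add(gene_id)
            continue
        if row.feature != "transcript":
            continue
        if row.strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {gene_id}: unknown strand {row.strand!r}")
        tss = int(row.start) - 1 if row.strand == "+" else int(row.end) - 1
        model = GeneModel(gene_id, str(row.seqname), row.strand, tss)
        if gene_id not in genes:
            genes[gene_id] = model
        elif canonical_rule == "five_prime_most":
            old = genes[gene_id]
            if (row.strand == "+" and tss < old.tss) or (
                row.strand == "-" and tss > old.tss
            ):
                genes[gene_id] = model
        # first_transcript: keep the existing entry
    orphans = seen_gene_features - set(genes)
    if orphans:
        logger.warning(
            "%d gene feature(s) without transcript skipped (e.g. %s)",
            len(orphans), sorted(orphans)[0],
        )
    return list(genes.values())


def write_gtf(
    genes: Iterable[GeneModel], path: str | Path, transcript_length: int = 1000
) -> None:
    """Write gene models as gene+transcript GTF records.

    Each gene becomes a transcript of ``transcript_length`` bp starting at its
    TSS (extending 3'), converted back to 1-based inclusive coordinates.
    """
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                start, end = g.tss + 1, g.tss + transcript_length
            else:
                start, end = max(1, g.tss + 2 - transcript_length), g.tss + 1
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            for feature in ("gene", "transcript"):
                fh.write(
                    f"{g.contig}\tatacmotif\t{feature}\t{start}\t{end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# JASPAR-style PFM
# ---------------------------------------------------------------------------

def read_pfm(path: str | Path):
    """Read a JASPAR-style position frequency matrix.

    Accepts both dialects commonly found in the wild::

        >MOTIF            >MOTIF
        A 4 0             A [ 4 0 ]
        C 0 4             C [ 0 4 ]
        ...               ...

    Rows must be labelled A, C, G, T in that order, equal length,
    non-negative counts. Returns a :class:`~atacmotif.motifs.PositionCountMatrix`.
    """
    from .motifs import PositionCountMatrix

    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty PFM file")
    name = "motif"
    if lines[0].startswith(">"):
        name = lines[0][1:].split()[0] if lines[0][1:].split() else "motif"
        lines = lines[1:]
    if len(lines) < 4:
        raise FormatError(f"{path}: expected four base rows (A, C, G, T)")
    rows = []
    for expected_base, line in zip("ACGT", lines[:4]):
        tokens = line.replace("[", " ").replace("]", " ").split()
        if not tokens or tokens[0].upper() != expected_base:
            raise FormatError(
                f"{path}: expected row labelled {expected_base}, got {line!r}"
            )
        try:
            values = [float(tok) for tok in tokens[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric count in row {expected_base}") from exc
        if any(v < 0 for v in values):
            raise FormatError(f"{path}: negative count in row {expected_base}")
        rows.append(values)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged rows (lengths {sorted(lengths)})")
    if lengths == {0}:
        raise FormatError(f"{path}: zero-length matrix")
    return PositionCountMatrix(np.asarray(rows, dtype=float), motif_name=name)


def write_pfm(pcm, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pcm.motif_name}\n")
        for base, row in zip("ACGT", pcm.counts):
            joined = " ".join(f"{v:g}" for v in row)
            fh.write(f"{base} [ {joined} ]\n")


# ---------------------------------------------------------------------------
# Differential tables
# ---------------------------------------------------------------------------

def read_differential_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV differential table with header.

    Requires columns ``id``, ``log2fc`` and at least one of ``fdr`` /
    ``padj`` (normalised to ``fdr``); peak tables additionally carry
    ``contig``, ``start``, ``end``.
    """
    df = pd.read_csv(str(path), sep="\t")
    if "padj" in df.columns and "fdr" not in df.columns:
        df = df.rename(columns={"padj": "fdr"})
    missing = {"id", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise FormatError(f"{path}: duplicate id {dup!r}")
    return df
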