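"""Threshold filters for differential peak and gene tables.

The filters reproduce the stated selection rules for treatment-dependent
chromatin and differentially expressed genes: peaks pass at FDR <= fdr_max
with fold change strictly greater than fc_min (more-accessible-in-treatment)
or strictly less than -fc_min (more-accessible-in-control); genes pass at
adjusted p < adj_p_max split by the sign of log2 fold change. Fold-change
boundaries are strict and the FDR boundary inclusive, read literally from
the rule's symbols. The fold-change scale defaults to log2 (so fc_min=1
means a 2x linear change); a linear reading is available via ``fc_scale``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .types import FormatError, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = ["DifferentialPeakSet", "filter_differential_peaks", "filter_differential_genes"]

_PEAK_COLUMNS = {"id", "contig", "start", "end", "log2fc", "fdr"}


@dataclass
class DifferentialPeakSet:
    """Peaks split into treatment-up and treatment-down sets."""

    up: pd.DataFrame
    down: pd.DataFrame
    fdr_max: float
    fc_min: float
    fc_scale: str

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    def up_intervals(self) -> list[GenomicInterval]:
        return _to_intervals(self.up)

    def down_intervals(self) -> list[GenomicInterval]:
        return _to_intervals(self.down)


def _to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(r.contig), int(r.start), int(r.end), name=str(r.id))
        for r in df.itertuples(index=False)
    ]


def filter_differential_peaks(
    records: pd.DataFrame,
    fdr_max: float = 0.05,
    fc_min: float = 1.0,
    fc_scale: str = "log2",
) -> DifferentialPeakSet:
    """Select differentially accessible peaks from a table of test results.

    ``records`` needs columns id, contig, start, end, log2fc, fdr. With
    ``fc_scale="log2"`` the rule is ``fdr <= fdr_max and |log2fc| > fc_min``
    (sign selects up vs down); with ``"linear"`` the log2fc column is
    exponentiated to a signed linear fold change before comparison.
    """
    if fc_scale not in ("log2", "linear"):
        raise ValueError(f"unknown fc_scale {fc_scale!r}")
    missing = _PEAK_COLUMNS - set(records.columns)
    if missing:
        raise FormatError(f"peak table missing columns {sorted(missing)}")
    if records[["log2fc", "fdr"]].isna().any().any():
        bad = records.loc[records[["log2fc", "fdr"]].isna().any(axis=1), "id"].iloc[0]
        raise FormatError(f"record {bad!r} has missing log2fc/fdr")
    fc = records["log2fc"].astype(float)
    if fc_scale == "linear":
        # signed linear fold change: 2**|lfc| with the sign of lfc
        fc = fc.apply(lambda v: 2.0 ** abs(v) * (1 if v >= 0 else -1))
    sig = records["fdr"].astype(float) <= fdr_max
    up = records[sig & (fc > fc_min)].reset_index(drop=True)
    down = records[sig & (fc < -fc_min)].reset_index(drop=True)
    logger.info(
        "differential peaks: %d up, %d down (fdr<=%g, fc>%g on %s scale)",
        len(up), len(down), fdr_max, fc_min, fc_scale,
    )
    return DifferentialPeakSet(up=up, down=down, fdr_max=fdr_max, fc_min=fc_min, fc_scale=fc_scale)


def filter_differential_genes(
    records: pd.DataFrame, adj_p_max: float = 0.05
) -> tuple[list[str], list[str]]:
    """Split genes into (up, down) id lists at adjusted p < adj_p_max.

    Genes with a significant adjusted p but log2fc exactly 0 belong to
    neither set; a warning reports how many were dropped that way.
    """
    missing = {"id", "log2fc", "fdr"} - set(records.columns)
    if missing:
        raise FormatError(f"gene table missing columns {sorted(missing)}")
    sig = records["fdr"].astype(float) < adj_p_max
    lfc = records["log2fc"].astype(float)
    up = records.loc[sig & (lfc > 0), "id"].astype(str).tolist()
    down = records.loc[sig & (lfc < 0), "id"].astype(str).tolist()
    n_zero = int((sig & (lfc == 0)).sum())
    if n_zero:
        logger.warning("%d significant gene(s) with log2fc == 0 assigned to neither set", n_zero)
    return up, down
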