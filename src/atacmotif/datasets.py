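"""Packaged example motif matrices.

These are synthetic stand-ins with plausible consensus cores (SOX9-like
AACAAT HMG box, GLI1-like GACCACCC, ZEB1-like CACCTG E-box, CTCF-like
GC-rich zinc-finger core), invented for demonstrations and simulation; they
are not database matrices. Real analyses should supply their own PFMs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

__all__ = ["example_motif_paths", "example_motifs"]


def example_motif_paths() -> dict[str, Path]:
    """Name -> path of the packaged synthetic PFM files."""
    root = resources.files("atacmotif") / "data" / "motifs"
    return {p.name.split("_")[0]: Path(str(p)) for p in sorted(root.iterdir()) if p.name.endswith(".pfm")}


def example_motifs() -> dict[str, "PositionCountMatrix"]:  # noqa: F821
    """Name -> parsed :class:`PositionCountMatrix` for the packaged examples."""
    from .io import read_pfm

    return {name: read_pfm(path) for name, path in example_motif_paths().items()}
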