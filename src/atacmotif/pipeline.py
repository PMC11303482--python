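"""End-to-end orchestration: filter -> scan -> enrich -> profile -> integrate.

A :class:`PipelineConfig` (usually loaded from YAML) names the inputs and
thresholds; :func:`run_pipeline` executes the stages, writes machine-readable
outputs (TSV/JSON/BED) into the output directory, and returns the report
dictionary. Outputs are deterministic for a fixed config: the run manifest
records a hash of the canonical config, the seed and the package version,
and contains no timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import filter_differential_genes, filter_differential_peaks
from .enrichment import motif_fraction_summary, multi_tf_enrichment
from .integration import (
    assign_peaks_to_promoters,
    candidate_direct_targets,
    tss_metaprofile,
)
from .io import read_differential_table, read_fasta, read_pfm, read_tss_from_gtf, write_bed
from .motifs import BackgroundModel, build_pwm, calibrate_threshold, peaks_with_motif

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    genome: str
    peaks: str  # differential peak TSV (id, contig, start, end, log2fc, pvalue, fdr)
    gtf: str
    motifs: list[str]  # PFM paths; the first motif drives the integration stage
    gene_table: str
    outdir: str = "atacmotif_out"
    fdr_max: float = 0.05
    fc_min: float = 1.0
    fc_scale: str = "log2"
    alpha: float = 1e-4
    pseudocount: float = 0.8
    n_perm: int = 1000
    seed: int = 0
    exclude_peaks: bool = False  # peak-avoiding null sampling
    gc_match: float | None = None
    window_bp: int = 5000
    tss_window: int = 1000
    n_bins: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        flat: dict = {}
        for key, value in raw.items():
            if key in ("thresholds", "enrichment", "integration") and isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        return cls(**flat)

    def validate(self) -> None:
        for label in ("genome", "peaks", "gtf", "gene_table"):
            p = getattr(self, label)
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        for m in self.motifs:
            if not Path(m).exists():
                raise FileNotFoundError(f"motif path does not exist: {m}")
        if not self.motifs:
            raise ValueError("at least one motif PFM is required")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha outside (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def canonical(self) -> dict:
        return {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage: load inputs")
    genome = read_fasta(config.genome)
    peak_table = read_differential_table(config.peaks)
    gene_models = read_tss_from_gtf(config.gtf)
    gene_table = read_differential_table(config.gene_table)
    bg = BackgroundModel.from_genome(genome)
    pwms = {}
    for mpath in config.motifs:
        pcm = read_pfm(mpath)
        if pcm.motif_name in pwms:
            raise ValueError(f"duplicate motif name {pcm.motif_name!r}")
        pwms[pcm.motif_name] = calibrate_threshold(
            build_pwm(pcm, bg, pseudocount=config.pseudocount), alpha=config.alpha
        )

    logger.info("stage: filter differential tables")
    peak_set = filter_differential_peaks(
        peak_table, fdr_max=config.fdr_max, fc_min=config.fc_min, fc_scale=config.fc_scale
    )
    up_peaks = peak_set.up_intervals()
    write_bed(up_peaks, outdir / "peaks_up.bed")
    write_bed(peak_set.down_intervals(), outdir / "peaks_down.bed")
    up_genes, down_genes = filter_differential_genes(gene_table, adj_p_max=config.fdr_max)

    logger.info("stage: scan peaks for motifs")
    primary_name, primary_pwm = next(iter(pwms.items()))
    flags, motif_count, _ = peaks_with_motif(up_peaks, genome, primary_pwm)
    count, percent = motif_fraction_summary(flags)
    flag_df = pd.DataFrame(
        {"peak": [p.name for p in up_peaks], "has_motif": flags.astype(int)}
    )
    flag_df.to_csv(outdir / "peak_motif_flags.tsv", sep="\t", index=False)

    logger.info("stage: permutation enrichment (%d motifs)", len(pwms))
    enr = multi_tf_enrichment(
        up_peaks,
        genome,
        pwms,
        n_perm=config.n_perm,
        seed=config.seed,
        exclusions=up_peaks if config.exclude_peaks else None,
        gc_match=config.gc_match,
    )
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    _dump_json(enr.to_dict(orient="records"), outdir / "enrichment.json")

    logger.info("stage: TSS metaprofile")
    profile = tss_metaprofile(
        up_peaks, gene_models, genome.lengths,
        window=config.tss_window, n_bins=config.n_bins,
    )
    prof_df = pd.DataFrame(profile.matrix, index=profile.gene_ids)
    prof_df.to_csv(outdir / "tss_profile.tsv", sep="\t")
    np.savetxt(outdir / "tss_profile_mean.tsv", profile.column_means, fmt="%.6f")

    logger.info("stage: promoter integration")
    mapping = assign_peaks_to_promoters(up_peaks, gene_models, max_dist=config.window_bp)
    flag_map = {p.name: bool(f) for p, f in zip(up_peaks, flags)}
    integration = candidate_direct_targets(
        up_genes, mapping, flag_map, window_bp=config.window_bp
    )
    _dump_json(integration.to_dict(), outdir / "integration.json")

    report = {
        "n_up_peaks": peak_set.n_up,
        "n_down_peaks": peak_set.n_down,
        "n_up_genes": len(up_genes),
        "n_down_genes": len(down_genes),
        "primary_motif": primary_name,
        "motif_peak_count": count,
        "motif_peak_percent": percent,
        "n_with_proximal_peak": integration.n_with_proximal_peak,
        "n_with_motif_peak": integration.n_with_motif_peak,
        "enrichment": enr.drop(columns=["null_sd", "z"]).to_dict(orient="records"),
        "manifest": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "config": config.canonical(),
        },
    }
    _dump_json(report, outdir / "report.json")
    return report
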