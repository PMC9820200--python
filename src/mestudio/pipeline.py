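"""Single-command orchestration of the full analysis.

Stages run in method order — seqid normalization and validation, motif
scanning, feature partitioning, crossing, statistics, plots — and each
stage writes its intermediates as GFF3 so the stages can also be run
individually and composed (running them separately is byte-identical to
the single pipeline call for all non-image outputs). Every run writes a
machine-readable manifest of inputs and parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .crosser_stats import (cross, crossed_to_gff, make_bed, make_chrom,
                            summarize, write_stats_log)
from .feature_map import (CATEGORIES, FULL_GAP, UpstreamPolicy,
                          derive_features, features_to_gff, partition_report)
from .formats_io import (read_fasta, read_gff3_annotation,
                         read_gff3_methylation, read_motifs, read_roary,
                         write_bed, write_gff3)
from .motif_core import matches_to_gff, scan_genome
from .preprocess import DEFAULT_RULES, normalize_seqids, validate_inputs
from .viz import DEFAULT_WINDOW_BP, plot_circular, plot_heatmap, plot_scatter

logger = logging.getLogger("mestudio")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    fasta: Path
    annotation: Path
    methylation: Path
    motifs: Path
    outdir: Path
    upstream_range: int | None = None   # None -> full-gap US definition
    make_chrom: bool = False
    make_bed: bool = True
    roary: Path | None = None
    only_methylated: bool = False
    window_bp: int = DEFAULT_WINDOW_BP
    seqid_rules: tuple[tuple[str, str], ...] = DEFAULT_RULES
    make_plots: bool = True
    dpi: int = 150

    @property
    def policy(self) -> UpstreamPolicy:
        if self.upstream_range is None:
            return FULL_GAP
        return UpstreamPolicy.fixed(self.upstream_range)


def _manifest(config: RunConfig) -> dict:
    return {
        "tool": "mestudio",
        "version": __version__,
        "inputs": {
            "fasta": str(config.fasta),
            "annotation": str(config.annotation),
            "methylation": str(config.methylation),
            "motifs": str(config.motifs),
            "roary": str(config.roary) if config.roary else None,
        },
        "parameters": {
            "upstream_range": config.upstream_range,
            "window_bp": config.window_bp,
            "seqid_rules": [list(r) for r in config.seqid_rules],
            "only_methylated": config.only_methylated,
            "make_chrom": config.make_chrom,
            "make_bed": config.make_bed,
        },
    }


def run(config: RunConfig) -> dict:
    """Run the whole pipeline; returns a result dict with the summary
    and paths of everything written."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- preprocess: harmonize seqids, validate coordinates -------------
    norm_dir = outdir / "normalized"
    fasta_c, ann_c, meth_c, seqid_report = normalize_seqids(
        config.fasta, config.annotation, config.methylation, norm_dir,
        config.seqid_rules)
    validate_inputs(fasta_c, ann_c, meth_c)

    replicons = read_fasta(fasta_c)
    genes = read_gff3_annotation(ann_c)
    meth = read_gff3_methylation(meth_c)
    motifs = read_motifs(config.motifs)

    # --- motif scanning -------------------------------------------------
    matches = scan_genome(replicons, motifs)
    match_dir = outdir / "matches"
    match_dir.mkdir(exist_ok=True)
    for motif, hits in matches.items():
        write_gff3(matches_to_gff(hits), match_dir / f"{motif}_matches.gff3")

    # --- feature partitioning -------------------------------------------
    features = derive_features(replicons, genes, config.policy)
    lengths = {r.seqid: r.length for r in replicons}
    by_rep: dict[str, list] = {r.seqid: [] for r in replicons}
    for cat in ("CDS", "US", "tIG"):
        for f in features[cat]:
            by_rep[f.seqid].append(f)
    for sid, ivs in by_rep.items():
        partition_report(ivs, lengths[sid], sid, overlapping_ok=True)
    feat_dir = outdir / "features"
    feat_dir.mkdir(exist_ok=True)
    for cat in CATEGORIES:
        write_gff3(features_to_gff(features[cat]), feat_dir / f"{cat}.gff3")

    # --- crossing --------------------------------------------------------
    crossed = cross(meth, matches, features, genes)
    crossed_dir = outdir / "crossed"
    crossed_dir.mkdir(exist_ok=True)
    for motif, per_cat in crossed.items():
        for cat, records in per_cat.items():
            write_gff3(crossed_to_gff(records),
                       crossed_dir / f"{motif}_{cat}.gff3")
    if config.make_chrom:
        chrom_dir = outdir / "chromosomes"
        chrom_dir.mkdir(exist_ok=True)
        for sid, rows in make_chrom(crossed, [r.seqid for r in replicons]
                                    ).items():
            write_gff3(rows, chrom_dir / f"{sid}.gff3")

    # --- statistics ------------------------------------------------------
    roary = read_roary(config.roary) if config.roary else None
    summary = summarize(crossed, genes, features, roary)
    write_stats_log(summary, outdir / "mestudio.log")

    bed_tables = make_bed(crossed, genes, features, config.only_methylated)
    if config.make_bed:
        bed_dir = outdir / "bed"
        bed_dir.mkdir(exist_ok=True)
        for cat, rows in bed_tables.items():
            note = ("US/tIG rows carry interval coordinates; owner geneID "
                    "(pair for tIG)") if cat in ("US", "tIG") else None
            write_bed(rows, bed_dir / f"{cat}.bed", note)

    # --- plots ------------------------------------------------------------
    if config.make_plots:
        plot_dir = outdir / "plots"
        plot_scatter(bed_tables, plot_dir, config.dpi)
        heat_counts = {
            motif: {"run": sum(len(v) for v in per_cat.values())}
            for motif, per_cat in crossed.items()
        }
        plot_heatmap(heat_counts, plot_dir, config.dpi)
        merged = {cat: [r for per_cat in crossed.values()
                        for r in per_cat[cat]] for cat in CATEGORIES}
        plot_circular(merged, replicons, genes, config.window_bp,
                      plot_dir, dpi=config.dpi)

    manifest = _manifest(config)
    manifest["seqid_mapping"] = seqid_report.mapping
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "summary": summary,
        "matches": matches,
        "features": features,
        "crossed": crossed,
        "bed": bed_tables,
        "outdir": outdir,
    }
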