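"""Graphical outputs: per-category scatter plots of methylations per
gene, a motif-by-strain heatmap scaled to each row's maximum, and
circular per-category density plots.

Every plot writes a numeric TSV twin alongside the image; all numeric
testing targets the TSV, images are only checked for existence. Ring
colors on the circular plot follow the category palette: CDS red,
nCDS blue, tIG purple, US yellow.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .crosser_stats import CrossedRecord
from .feature_map import CATEGORIES, FeatureInterval
from .formats_io import BedRow, RepliconSequence

CATEGORY_COLORS = {"CDS": "tab:red", "nCDS": "tab:blue",
                   "tIG": "purple", "US": "gold"}

DEFAULT_WINDOW_BP = 10_000


def plot_scatter(
    bed_tables: Mapping[str, Sequence[BedRow]],
    outdir: str | Path,
    dpi: int = 150,
) -> dict[str, Path]:
    """One scatter plot per category: gene index on Y, methylation count
    on X. The (geneID, count) table behind each plot is written as a TSV
    twin so the plot is testable numerically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for cat, rows in bed_tables.items():
        df = pd.DataFrame(
            [(r.gene_id, r.meth_count) for r in rows],
            columns=["geneID", "n_methylations"],
        )
        tsv = outdir / f"scatter_{cat}.tsv"
        df.to_csv(tsv, sep="\t", index=False)

        fig, ax = plt.subplots(figsize=(6, max(3, min(10, len(df) * 0.12))))
        if len(df):
            ax.scatter(df["n_methylations"], range(len(df)),
                       s=12, color=CATEGORY_COLORS.get(cat, "black"))
            ax.set_yticks(range(len(df)))
            ax.set_yticklabels(df["geneID"], fontsize=4)
        ax.set_xlabel("number of methylations")
        ax.set_ylabel("geneID")
        ax.set_title(f"methylated sites per gene — {cat}")
        fig.tight_layout()
        img = outdir / f"scatter_{cat}.png"
        fig.savefig(img, dpi=dpi)
        plt.close(fig)
        written[cat] = tsv
    return written


def scale_rows_to_max(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row by its maximum so values lie in [0, 1]; all-zero
    rows stay all-zero (no division blow-up)."""
    maxima = matrix.max(axis=1).replace(0, np.nan)
    return matrix.div(maxima, axis=0).fillna(0.0)


def plot_heatmap(
    counts: Mapping[str, Mapping[str, int]],
    outdir: str | Path,
    dpi: int = 150,
) -> Path:
    """Motif-by-strain heatmap of occurrence counts, each row scaled as a
    ratio to its maximum. ``counts``: motif -> strain -> count."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = pd.DataFrame(counts).T.fillna(0)  # rows = motifs
    matrix = matrix[sorted(matrix.columns)]
    scaled = scale_rows_to_max(matrix)
    tsv = outdir / "heatmap.tsv"
    scaled.to_csv(tsv, sep="\t", index_label="motif")

    fig, ax = plt.subplots(
        figsize=(max(3, 0.8 * len(matrix.columns) + 2),
                 max(3, 0.3 * len(matrix) + 1)))
    im = ax.imshow(scaled.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0, vmax=1)
    ax.set_xticks(range(len(scaled.columns)))
    ax.set_xticklabels(scaled.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(scaled)))
    ax.set_yticklabels(scaled.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="ratio to row max")
    fig.tight_layout()
    fig.savefig(outdir / "heatmap.png", dpi=dpi)
    plt.close(fig)
    return tsv


def window_counts(
    crossed_by_category: Mapping[str, Sequence[CrossedRecord]],
    replicons: Sequence[RepliconSequence],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Bin crossed records into genome windows: one row per (seqid,
    window) with per-category counts. Column sums equal the total number
    of crossed records per category."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for rep in replicons:
        n_win = max(1, math.ceil(rep.length / window_bp))
        for w in range(n_win):
            rows.append({
                "seqid": rep.seqid,
                "window_start": w * window_bp + 1,
                "window_end": min((w + 1) * window_bp, rep.length),
                **{c: 0 for c in CATEGORIES},
            })
    index = {}
    offset = 0
    win_per_rep = {}
    for rep in replicons:
        index[rep.seqid] = offset
        win_per_rep[rep.seqid] = max(1, math.ceil(rep.length / window_bp))
        offset += win_per_rep[rep.seqid]
    for cat, records in crossed_by_category.items():
        for r in records:
            w = (r.position - 1) // window_bp
            rows[index[r.seqid] + w][cat] += 1
    return pd.DataFrame(rows)


def plot_circular(
    crossed_by_category: Mapping[str, Sequence[CrossedRecord]],
    replicons: Sequence[RepliconSequence],
    genes: Sequence[FeatureInterval] | Sequence = (),
    window_bp: int = DEFAULT_WINDOW_BP,
    outdir: str | Path = ".",
    name: str = "circular",
    dpi: int = 150,
) -> Path:
    """Circular density plot: the genome laid out on a circle, an outer
    ring marking CDS positions, and four inner rings with per-window
    methylation counts per category (empty rings drawn blank)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = window_counts(crossed_by_category, replicons, window_bp)
    tsv = outdir / f"{name}.tsv"
    df.to_csv(tsv, sep="\t", index=False)

    genome_len = sum(r.length for r in replicons)
    offsets = {}
    off = 0
    for r in replicons:
        offsets[r.seqid] = off
        off += r.length

    fig = plt.figure(figsize=(7, 7))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_axis_off()

    def theta(seqid: str, pos: int) -> float:
        return 2 * math.pi * (offsets[seqid] + pos) / max(1, genome_len)

    # outer ring: CDS positions from the annotation
    for g in genes:
        t0 = theta(g.seqid, getattr(g, "start", 0))
        t1 = theta(g.seqid, getattr(g, "end", 0))
        ax.bar((t0 + t1) / 2, 0.06, width=max(t1 - t0, 1e-4), bottom=1.0,
               color="black", linewidth=0)

    radius = 0.9
    for cat in CATEGORIES:
        vals = df[cat].to_numpy(dtype=float)
        vmax = vals.max() if len(vals) and vals.max() > 0 else 1.0
        thetas = [
            theta(row.seqid, (row.window_start + row.window_end) // 2)
            for row in df.itertuples()
        ]
        widths = [
            max(theta(row.seqid, row.window_end)
                - theta(row.seqid, row.window_start), 1e-4)
            for row in df.itertuples()
        ]
        ax.bar(thetas, 0.14 * vals / vmax, width=widths,
               bottom=radius - 0.16, color=CATEGORY_COLORS[cat],
               linewidth=0, label=cat)
        radius -= 0.18
    ax.legend(loc="center", fontsize=8, frameon=False)
    ax.set_ylim(0, 1.1)
    fig.savefig(outdir / f"{name}.png", dpi=dpi)
    plt.close(fig)
    return tsv
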