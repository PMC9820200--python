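"""Cross methylation calls with motif matches and feature categories.

A methylation record enters motif M's output iff its position falls
inside an occurrence of M on the record's strand (records with strand
"." are matched permissively against either strand). Category assignment
is strand-aware:

* inside a gene body: record strand == gene strand -> **CDS**,
  otherwise -> **nCDS**;
* in an intergap: a same-strand US interval containing the position
  -> **US**, otherwise -> **tIG**.

Each record maps to exactly one category per motif under non-overlapping
annotations. A methylation inside overlapping gene bodies is credited to
every overlapping gene (one crossed record per gene, logged); summary
totals count *records*, not record-gene pairs, so conservation between
inputs and outputs stays checkable.

Downstream products: per-(motif, category) GFF3s, chromosome-level GFF3s
(same rows regrouped by seqid), per-category BED tables with per-gene
methylation counts, a human-readable statistics log, and optional Roary
core/dispensable labels.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .feature_map import CATEGORIES, FeatureInterval
from .formats_io import (BedRow, GeneRecord, GffFeature, MethylationRecord,
                         RoaryTable, parse_gff_attributes)
from .motif_core import MotifMatch

logger = logging.getLogger("mestudio")


@dataclass(frozen=True)
class CrossedRecord:
    """A methylation record attributed to one motif, category and gene."""

    seqid: str
    position: int
    strand: str
    mod_type: str
    attributes: str
    motif: str
    category: str
    gene_id: str  # empty for ownerless tIG; 'left|right' pair for tIG gaps
    product: str = ""

    def site_key(self) -> tuple:
        """Identity of the underlying methylation record (for counting
        records rather than record-gene pairs)."""
        return (self.seqid, self.position, self.strand, self.mod_type)


def _strand_ok(rec_strand: str, other: str) -> bool:
    return rec_strand == "." or other == "." or rec_strand == other


class _IntervalIndex:
    """Stabbing queries over (start, end, payload) spans via bisect;
    handles overlapping spans by tracking the maximum span width."""

    def __init__(self, spans: Iterable[tuple[int, int, object]]):
        self.spans = sorted(spans, key=lambda s: (s[0], s[1]))
        self.starts = [s[0] for s in self.spans]
        self.max_w = max((e - s + 1 for s, e, _ in self.spans), default=0)

    def stab(self, pos: int) -> list:
        """All payloads whose span contains pos."""
        out = []
        i = bisect_right(self.starts, pos) - 1
        lo = pos - self.max_w  # spans starting before this cannot reach pos
        while i >= 0 and self.starts[i] > lo:
            s, e, payload = self.spans[i]
            if s <= pos <= e:
                out.append(payload)
            i -= 1
        out.reverse()
        return out


def cross(
    meth: Sequence[MethylationRecord],
    matches: Mapping[str, Sequence[MotifMatch]],
    features: Mapping[str, Sequence[FeatureInterval]],
    genes: Sequence[GeneRecord] = (),
) -> dict[str, dict[str, list[CrossedRecord]]]:
    """Cross methylation records with motif matches and feature intervals.

    Returns motif -> category -> crossed records. ``genes`` (optional)
    supplies protein products for the output records. Records on a seqid
    absent from the feature map are a hard error — they should have been
    caught during preprocessing.
    """
    products = {g.gene_id: g.product for g in genes}
    known_seqids = {f.seqid for ivs in features.values() for f in ivs}
    known_seqids |= {g.seqid for g in genes}

    gene_idx: dict[str, _IntervalIndex] = {}
    by_rep_genes: dict[str, list] = defaultdict(list)
    for f in features.get("CDS", ()):
        by_rep_genes[f.seqid].append((f.start, f.end, f))
    for sid, spans in by_rep_genes.items():
        gene_idx[sid] = _IntervalIndex(spans)

    us_idx: dict[str, _IntervalIndex] = {}
    by_rep_us: dict[str, list] = defaultdict(list)
    for f in features.get("US", ()):
        by_rep_us[f.seqid].append((f.start, f.end, f))
    for sid, spans in by_rep_us.items():
        us_idx[sid] = _IntervalIndex(spans)

    tig_idx: dict[str, _IntervalIndex] = {}
    by_rep_tig: dict[str, list] = defaultdict(list)
    for f in features.get("tIG", ()):
        by_rep_tig[f.seqid].append((f.start, f.end, f))
    for sid, spans in by_rep_tig.items():
        tig_idx[sid] = _IntervalIndex(spans)

    result: dict[str, dict[str, list[CrossedRecord]]] = {}
    for motif, mmatches in matches.items():
        match_idx: dict[str, _IntervalIndex] = {}
        by_rep_m: dict[str, list] = defaultdict(list)
        for m in mmatches:
            by_rep_m[m.seqid].append((m.start, m.end, m))
        for sid, spans in by_rep_m.items():
            match_idx[sid] = _IntervalIndex(spans)

        out: dict[str, list[CrossedRecord]] = {c: [] for c in CATEGORIES}
        for rec in meth:
            if known_seqids and rec.seqid not in known_seqids:
                raise ValueError(
                    f"methylation record on unknown seqid {rec.seqid!r} "
                    "(inputs were not normalized/validated)"
                )
            idx = match_idx.get(rec.seqid)
            if idx is None:
                continue
            hit = any(_strand_ok(rec.strand, m.strand)
                      for m in idx.stab(rec.position))
            if not hit:
                continue
            _categorize(rec, motif, gene_idx.get(rec.seqid),
                        us_idx.get(rec.seqid), tig_idx.get(rec.seqid),
                        products, out)
        result[motif] = out
    return result


def _categorize(rec, motif, gidx, uidx, tidx, products, out) -> None:
    bodies = gidx.stab(rec.position) if gidx else []
    if bodies:
        if len(bodies) > 1:
            logger.info("position %s:%d lies in %d overlapping genes; "
                        "credited to each", rec.seqid, rec.position,
                        len(bodies))
        for body in bodies:
            cat = "CDS" if _strand_ok(rec.strand, body.strand) else "nCDS"
            out[cat].append(CrossedRecord(
                rec.seqid, rec.position, rec.strand, rec.mod_type,
                rec.attributes, motif, cat, body.owner_gene_id,
                products.get(body.owner_gene_id, "")))
        return
    us_hits = [f for f in (uidx.stab(rec.position) if uidx else [])
               if _strand_ok(rec.strand, f.strand)]
    if us_hits:
        f = us_hits[0]
        out["US"].append(CrossedRecord(
            rec.seqid, rec.position, rec.strand, rec.mod_type,
            rec.attributes, motif, "US", f.owner_gene_id,
            products.get(f.owner_gene_id, "")))
        return
    tig_hits = (tidx.stab(rec.position) if tidx else [])
    owner = tig_hits[0].owner_gene_id if tig_hits else ""
    out["tIG"].append(CrossedRecord(
        rec.seqid, rec.position, rec.strand, rec.mod_type,
        rec.attributes, motif, "tIG", owner, ""))


# ---------------------------------------------------------------------------
# GFF3 serialization of crossed records
# ---------------------------------------------------------------------------

def crossed_to_gff(records: Iterable[CrossedRecord]) -> list[GffFeature]:
    """Crossed records as GFF3 rows: the original modified-base layout
    with category=/motif=/gene= keys appended to the attributes."""
    rows = []
    for r in records:
        attrs = r.attributes.rstrip(";")
        extra = f"motif={r.motif};category={r.category};gene={r.gene_id}"
        attrs = f"{attrs};{extra}" if attrs else extra
        rows.append(GffFeature(r.seqid, "mestudio", r.mod_type, r.position,
                               r.position, ".", r.strand, ".", attrs))
    return rows


def make_chrom(
    crossed: Mapping[str, Mapping[str, Sequence[CrossedRecord]]],
    seqids: Sequence[str],
) -> dict[str, list[GffFeature]]:
    """Regroup crossed records by replicon instead of category.

    Every seqid in ``seqids`` gets an entry, possibly empty (so a
    header-only GFF3 is still written and downstream globs stay
    deterministic). Row multisets are conserved between the feature-level
    and chromosome-level groupings.
    """
    out: dict[str, list[GffFeature]] = {sid: [] for sid in seqids}
    for per_cat in crossed.values():
        for records in per_cat.values():
            for row in crossed_to_gff(records):
                out.setdefault(row.seqid, []).append(row)
    for sid in out:
        out[sid].sort(key=lambda r: (r.start, r.strand, r.attributes))
    return out


# ---------------------------------------------------------------------------
# BED tables
# ---------------------------------------------------------------------------

def make_bed(
    crossed: Mapping[str, Mapping[str, Sequence[CrossedRecord]]],
    genes: Sequence[GeneRecord],
    features: Mapping[str, Sequence[FeatureInterval]],
    only_methylated: bool = False,
) -> dict[str, list[BedRow]]:
    """One BED table per category, merged over motifs.

    CDS/nCDS rows carry the gene body (0-based half-open) and the number
    of crossed records credited to that gene in that category; US and tIG
    rows carry the *interval's* own coordinates, with the owner geneID
    (a 'left|right' pair for tIG between genes). Genes with zero
    methylations are emitted with count 0 unless ``only_methylated``.
    """
    counts: dict[str, Counter] = {c: Counter() for c in CATEGORIES}
    pos_counts: dict[str, list[CrossedRecord]] = {c: [] for c in CATEGORIES}
    for per_cat in crossed.values():
        for cat, records in per_cat.items():
            for r in records:
                counts[cat][r.gene_id] += 1
                pos_counts[cat].append(r)

    products = {g.gene_id: g.product for g in genes}
    out: dict[str, list[BedRow]] = {}
    for cat in ("CDS", "nCDS"):
        rows = []
        for g in genes:
            n = counts[cat].get(g.gene_id, 0)
            if only_methylated and n == 0:
                continue
            rows.append(BedRow(g.seqid, g.start - 1, g.end, g.gene_id, n,
                               products.get(g.gene_id, "")))
        rows.sort(key=lambda r: (r.chrom, r.start))
        out[cat] = rows
    for cat in ("US", "tIG"):
        rows = []
        for f in features.get(cat, ()):
            n = sum(1 for r in pos_counts[cat]
                    if r.seqid == f.seqid and f.start <= r.position <= f.end)
            if only_methylated and n == 0:
                continue
            owner = f.owner_gene_id or "."
            prod = products.get(f.owner_gene_id, "")
            rows.append(BedRow(f.seqid, f.start - 1, f.end, owner, n, prod))
        rows.sort(key=lambda r: (r.chrom, r.start))
        out[cat] = rows
    return out


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass
class CategoryStats:
    n_features: int = 0          # genes (CDS/nCDS) or intervals (US/tIG)
    n_methylated_sites: int = 0  # distinct methylation records
    n_methylated_genes: int = 0
    top_gene_id: str = ""
    top_gene_product: str = ""
    top_gene_count: int = 0


@dataclass
class StatsSummary:
    per_category: dict[str, CategoryStats] = field(default_factory=dict)
    gene_labels: dict[str, str] = field(default_factory=dict)  # core/dispensable


def summarize(
    crossed: Mapping[str, Mapping[str, Sequence[CrossedRecord]]],
    genes: Sequence[GeneRecord],
    features: Mapping[str, Sequence[FeatureInterval]] | None = None,
    roary: RoaryTable | None = None,
) -> StatsSummary:
    """Per-category totals merged over motifs.

    n_methylated_sites counts distinct methylation records (a site inside
    two overlapping genes is one site). The most-methylated gene is the
    per-gene argmax, ties broken by lexicographic geneID so output is
    deterministic. With a Roary table, every methylated geneID is labeled
    core/dispensable ("unknown" with a warning when absent)."""
    products = {g.gene_id: g.product for g in genes}
    summary = StatsSummary()
    for cat in CATEGORIES:
        stats = CategoryStats()
        if cat in ("CDS", "nCDS"):
            stats.n_features = len(genes)
        elif features is not None:
            stats.n_features = len(features.get(cat, ()))
        sites: set[tuple] = set()
        per_gene: Counter = Counter()
        for per_cat in crossed.values():
            for r in per_cat.get(cat, ()):
                sites.add(r.site_key())
                if r.gene_id:
                    per_gene[r.gene_id] += 1
        stats.n_methylated_sites = len(sites)
        stats.n_methylated_genes = len(per_gene)
        if per_gene:
            # ties: smallest geneID among maxima
            best = max(per_gene.values())
            top = min(g for g, n in per_gene.items() if n == best)
            stats.top_gene_id = top
            stats.top_gene_count = per_gene[top]
            stats.top_gene_product = products.get(top, "")
        summary.per_category[cat] = stats

    if roary is not None:
        methylated_ids = {
            r.gene_id
            for per_cat in crossed.values()
            for recs in per_cat.values()
            for r in recs
            if r.gene_id and "|" not in r.gene_id
        }
        for gid in sorted(methylated_ids):
            label = roary.label_by_gene_id(gid)
            if label == "unknown":
                logger.warning("geneID %s not found in the Roary table", gid)
            summary.gene_labels[gid] = label
    return summary


def write_stats_log(summary: StatsSummary, path: str | Path) -> None:
    """Human-readable statistics log (per category: features, sites,
    methylated genes, most-methylated gene and product; then Roary
    labels when present)."""
    lines = ["# methylation summary by feature category", ""]
    for cat, s in summary.per_category.items():
        unit = "genes" if cat in ("CDS", "nCDS") else "intervals"
        lines += [
            f"[{cat}]",
            f"total {unit}: {s.n_features}",
            f"methylated sites: {s.n_methylated_sites}",
            f"methylated genes: {s.n_methylated_genes}",
            f"most methylated gene: {s.top_gene_id or '-'}"
            + (f" ({s.top_gene_count} sites)" if s.top_gene_id else ""),
            f"product: {s.top_gene_product or '-'}",
            "",
        ]
    if summary.gene_labels:
        lines.append("[pangenome]")
        for gid, label in summary.gene_labels.items():
            lines.append(f"{gid}: {label}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
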