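"""Partition each replicon into the four feature categories.

Categories, derived solely from the gene annotation:

* **CDS**  — the gene body on its own (sense) strand;
* **nCDS** — the same span considered on the antisense strand;
* **tIG**  — true intergenic: a gap whose flanking genes point in
  opposite directions (diverging or converging);
* **US**   — upstream sequence: a gap between two same-orientation
  genes, assigned to the downstream gene in reading orientation —
  the putative promoter region.

By default a US region is the whole gap between the end of one ORF and
the beginning of the next; a fixed upstream range clips each US to at
most ``range_bp`` adjacent to its owner's reading start, the remainder
being reclassified tIG.

Terminal gaps (before the first gene, after the last) are not covered by
the between-gene definitions and are decided here: the gap left of a
plus-strand first gene is that gene's US, the gap right of a
minus-strand last gene is that gene's US, and any other terminal gap is
tIG. Overlapping gene bodies win over intergap; the overlapped bp is CDS
of every overlapping gene and coverage checks then warn instead of fail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .formats_io import GeneRecord, RepliconSequence

logger = logging.getLogger("mestudio")

CATEGORIES = ("CDS", "nCDS", "tIG", "US")

Category = Literal["CDS", "nCDS", "tIG", "US"]


class PartitionError(ValueError):
    """Raised when CDS+US+tIG fail to tile the replicon exactly once."""


@dataclass(frozen=True)
class FeatureInterval:
    """A categorized span (1-based inclusive). ``owner_gene_id`` names the
    defining gene; for tIG between two genes it is 'left|right'; tIG has
    no intrinsic strand and carries '.'."""

    seqid: str
    start: int
    end: int
    strand: str          # "+", "-" or "." (tIG only)
    category: str
    owner_gene_id: str
    note: str = ""       # e.g. tIG sub-orientation: diverging/converging

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.category} interval [{self.start},{self.end}] inverted"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class UpstreamPolicy:
    """How far upstream of a gene its US region may extend.

    ``full_gap`` (the default) lets US occupy the whole inter-ORF gap;
    ``fixed_range`` clips it to ``range_bp`` next to the owner's start.
    """

    mode: Literal["full_gap", "fixed_range"] = "full_gap"
    range_bp: int = 0

    def __post_init__(self) -> None:
        if self.mode == "fixed_range" and self.range_bp <= 0:
            raise ValueError("fixed_range policy requires range_bp > 0")

    @classmethod
    def full_gap(cls) -> "UpstreamPolicy":
        return cls("full_gap")

    @classmethod
    def fixed(cls, range_bp: int) -> "UpstreamPolicy":
        return cls("fixed_range", range_bp)


FULL_GAP = UpstreamPolicy.full_gap()


def derive_cds(genes: Sequence[GeneRecord]) -> list[FeatureInterval]:
    """One CDS interval per gene: the gene's own coordinates and strand."""
    return [
        FeatureInterval(g.seqid, g.start, g.end, g.strand, "CDS", g.gene_id)
        for g in genes
    ]


def derive_ncds(genes: Sequence[GeneRecord]) -> list[FeatureInterval]:
    """One nCDS interval per gene: same coordinates, flipped strand."""
    flip = {"+": "-", "-": "+"}
    return [
        FeatureInterval(g.seqid, g.start, g.end, flip[g.strand], "nCDS",
                        g.gene_id)
        for g in genes
    ]


def _merged_bodies(genes: Sequence[GeneRecord]) -> list[tuple[int, int]]:
    """Union of gene bodies as disjoint sorted (start, end) spans."""
    spans = sorted((g.start, g.end) for g in genes)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _flank(genes: Sequence[GeneRecord], gap_start: int, gap_end: int
           ) -> tuple[GeneRecord | None, GeneRecord | None]:
    """Nearest gene body ending left of the gap / starting right of it."""
    left = None
    right = None
    for g in genes:
        if g.end < gap_start and (left is None or (g.end, g.gene_id) >
                                  (left.end, left.gene_id)):
            left = g
        if g.start > gap_end and (right is None or (g.start, g.gene_id) <
                                  (right.start, right.gene_id)):
            right = g
    return left, right


def _classify_gap(seqid: str, gap_start: int, gap_end: int,
                  left: GeneRecord | None, right: GeneRecord | None,
                  policy: UpstreamPolicy,
                  us_out: list[FeatureInterval],
                  tig_out: list[FeatureInterval]) -> None:
    def tig(s: int, e: int, owner: str, note: str = "") -> None:
        tig_out.append(FeatureInterval(seqid, s, e, ".", "tIG", owner, note))

    def us(s: int, e: int, owner: GeneRecord) -> None:
        # fixed-range clipping keeps the portion adjacent to the owner's
        # reading start; the remainder becomes tIG
        if policy.mode == "fixed_range":
            if owner.strand == "+":
                clip_s = max(s, e - policy.range_bp + 1)
                if clip_s > s:
                    tig(s, clip_s - 1, owner.gene_id, "us_overflow")
                s = clip_s
            else:
                clip_e = min(e, s + policy.range_bp - 1)
                if clip_e < e:
                    tig(clip_e + 1, e, owner.gene_id, "us_overflow")
                e = clip_e
        us_out.append(FeatureInterval(seqid, s, e, owner.strand, "US",
                                      owner.gene_id))

    if left is None and right is None:
        # no genes at all: nothing is genic or upstream-of-gene
        tig(gap_start, gap_end, "")
    elif left is None:  # gap before the first gene
        if right.strand == "+":
            us(gap_start, gap_end, right)
        else:
            tig(gap_start, gap_end, right.gene_id, "terminal")
    elif right is None:  # gap after the last gene
        if left.strand == "-":
            us(gap_start, gap_end, left)
        else:
            tig(gap_start, gap_end, left.gene_id, "terminal")
    elif left.strand == right.strand:
        # same orientation: upstream of the downstream gene in reading order
        owner = right if left.strand == "+" else left
        us(gap_start, gap_end, owner)
    else:
        note = "diverging" if left.strand == "-" else "converging"
        tig(gap_start, gap_end, f"{left.gene_id}|{right.gene_id}", note)


def derive_intergenic(
    genes: Sequence[GeneRecord],
    replicon_length: int,
    policy: UpstreamPolicy = FULL_GAP,
) -> tuple[list[FeatureInterval], list[FeatureInterval]]:
    """Classify every maximal inter-body gap of one replicon as (US, tIG).

    Gaps are the complement of the union of gene bodies, so overlapping
    annotations never leak genic bp into the intergenic sets.
    """
    if any(g.end > replicon_length for g in genes):
        raise ValueError("gene beyond replicon end; run validation first")
    seqid = genes[0].seqid if genes else ""
    us_out: list[FeatureInterval] = []
    tig_out: list[FeatureInterval] = []
    bodies = _merged_bodies(genes)
    if not genes:
        # degenerate: caller must supply seqid via a gene or handle empties;
        # an annotation-free replicon is a single tIG span
        return [], [FeatureInterval("", 1, replicon_length, ".", "tIG", "")]
    cursor = 1
    for s, e in bodies:
        if cursor <= s - 1:
            left, right = _flank(genes, cursor, s - 1)
            _classify_gap(seqid, cursor, s - 1, left, right, policy,
                          us_out, tig_out)
        cursor = e + 1
    if cursor <= replicon_length:
        left, right = _flank(genes, cursor, replicon_length)
        _classify_gap(seqid, cursor, replicon_length, left, right, policy,
                      us_out, tig_out)
    us_out.sort(key=lambda f: f.start)
    tig_out.sort(key=lambda f: f.start)
    return us_out, tig_out


def derive_features(
    replicons: Sequence[RepliconSequence],
    genes: Sequence[GeneRecord],
    policy: UpstreamPolicy = FULL_GAP,
) -> dict[str, list[FeatureInterval]]:
    """Full CDS/nCDS/tIG/US feature map for a whole genome, replicon by
    replicon, in FASTA order."""
    by_rep: dict[str, list[GeneRecord]] = {r.seqid: [] for r in replicons}
    for g in genes:
        if g.seqid not in by_rep:
            raise ValueError(f"gene {g.gene_id!r} on unknown seqid {g.seqid!r}")
        by_rep[g.seqid].append(g)
    out: dict[str, list[FeatureInterval]] = {c: [] for c in CATEGORIES}
    for rep in replicons:
        rep_genes = sorted(by_rep[rep.seqid], key=lambda g: (g.start, g.end))
        out["CDS"].extend(derive_cds(rep_genes))
        out["nCDS"].extend(derive_ncds(rep_genes))
        us, tig = derive_intergenic(rep_genes, rep.length, policy)
        if not rep_genes:
            # patch in the seqid the gene-free branch could not know
            tig = [FeatureInterval(rep.seqid, t.start, t.end, t.strand,
                                   t.category, t.owner_gene_id, t.note)
                   for t in tig]
        out["US"].extend(us)
        out["tIG"].extend(tig)
    return out


@dataclass
class CoverageReport:
    seqid: str
    replicon_length: int
    bp_by_category: dict[str, int]
    overlapping_genes: bool

    @property
    def covered_bp(self) -> int:
        return sum(v for k, v in self.bp_by_category.items() if k != "nCDS")


def partition_report(
    intervals: Iterable[FeatureInterval],
    replicon_length: int,
    seqid: str = "",
    overlapping_ok: bool = False,
) -> CoverageReport:
    """Assert CDS ∪ US ∪ tIG tiles [1, replicon_length] exactly once.

    nCDS is excluded (it duplicates CDS extents on the other strand).
    A gap or double-cover is a hard error unless ``overlapping_ok``, in
    which case CDS self-overlap (overlapping gene input) only warns.
    """
    ivs = [f for f in intervals if f.category != "nCDS"]
    bp = {c: 0 for c in CATEGORIES}
    for f in ivs:
        bp[f.category] += f.width
    bp["nCDS"] = bp["CDS"]
    ivs.sort(key=lambda f: (f.start, f.end))
    overlapping = False
    cursor = 1
    covered_to = 0
    for f in ivs:
        if f.start > cursor:
            raise PartitionError(
                f"{seqid}: gap [{cursor},{f.start - 1}] uncovered"
            )
        if f.start < cursor:
            overlapping = True
            if not overlapping_ok or f.category != "CDS":
                raise PartitionError(
                    f"{seqid}: {f.category} [{f.start},{f.end}] double-covers "
                    f"bp < {cursor}"
                )
        cursor = max(cursor, f.end + 1)
        covered_to = max(covered_to, f.end)
    if covered_to != replicon_length or cursor != replicon_length + 1:
        raise PartitionError(
            f"{seqid}: coverage ends at {covered_to}, replicon length "
            f"{replicon_length}"
        )
    if overlapping:
        logger.warning("%s: overlapping gene bodies; CDS bp double-counted",
                       seqid)
    return CoverageReport(seqid, replicon_length, bp, overlapping)


# ---------------------------------------------------------------------------
# serialization (one GFF3 per category, column 3 = category name)
# ---------------------------------------------------------------------------

def features_to_gff(intervals: Iterable[FeatureInterval]):
    from .formats_io import GffFeature
    rows = []
    for f in intervals:
        attrs = f"owner={f.owner_gene_id}"
        if f.note:
            attrs += f";note={f.note}"
        rows.append(GffFeature(f.seqid, "mestudio", f.category, f.start,
                               f.end, ".", f.strand, ".", attrs))
    return rows


def gff_to_features(features) -> list[FeatureInterval]:
    from .formats_io import parse_gff_attributes
    out = []
    for row in features:
        attrs = parse_gff_attributes(row.attributes)
        out.append(FeatureInterval(row.seqid, row.start, row.end, row.strand,
                                   row.ftype, attrs.get("owner", ""),
                                   attrs.get("note", "")))
    return out
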