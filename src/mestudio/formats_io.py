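"""Readers and writers for every external format the pipeline touches.

One canonical in-memory representation per format:

* FASTA genome            -> list of :class:`RepliconSequence`
* annotation GFF3         -> list of :class:`GeneRecord`
* SMRT modified-base GFF3 -> list of :class:`MethylationRecord`
* motif text file         -> :class:`MotifList`
* Roary presence/absence  -> :class:`RoaryTable`
* BED6-like output        -> list of :class:`BedRow`

GFF3 coordinates are 1-based inclusive throughout; BED output is 0-based
half-open. The GFF3 attributes column is carried byte-for-byte: the
pipeline appends its own keys (``category=``, ``motif=``) but never
rewrites keys produced upstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger("mestudio")

VALID_BASES = frozenset("ACGTN")

GFF_VERSION_HEADER = "##gff-version 3"

#: column count of a GFF3 body row
_GFF_NCOLS = 9

#: the 14 metadata columns that precede the per-strain columns in a
#: Roary gene_presence_absence.csv
ROARY_META_COLS = 14


class FormatError(ValueError):
    """Raised on any malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepliconSequence:
    """One named replicon/contig with its nucleotide string."""

    seqid: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"replicon {self.seqid!r}: non-nucleotide character(s) "
                f"{sorted(bad)!r} (allowed: A,C,G,T,N)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene/CDS row from a GFF3 annotation."""

    seqid: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # "+" or "-"
    gene_id: str
    product: str = ""
    source_line: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval "
                f"[{self.start},{self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be + or -")
        if not self.gene_id:
            raise FormatError("gene record with empty geneID")


@dataclass(frozen=True)
class MethylationRecord:
    """One modified-base call (SMRT Link dialect)."""

    seqid: str
    position: int  # 1-based bp of the modified base
    strand: str    # "+", "-" or "."
    mod_type: str  # e.g. m6A, m4C, modified_base
    attributes: str = ""  # column 9, passed through verbatim

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"methylation position {self.position} < 1")
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid methylation strand {self.strand!r}")


@dataclass(frozen=True)
class MotifList:
    """Ordered, duplicate-free list of IUPAC motif strings."""

    motifs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.motifs:
            raise FormatError("motif list is empty")
        seen: set[str] = set()
        from .motif_core import IUPAC_SETS  # deferred: avoids import cycle
        for m in self.motifs:
            if m in seen:
                raise FormatError(f"duplicate motif {m!r}")
            seen.add(m)
            bad = set(m) - set(IUPAC_SETS)
            if bad:
                raise FormatError(
                    f"motif {m!r}: invalid IUPAC code(s) {sorted(bad)!r}"
                )

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)


@dataclass(frozen=True)
class GffFeature:
    """A generic GFF3 body row (used for motif-match and crossed outputs)."""

    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    score: str
    strand: str
    frame: str
    attributes: str

    def to_line(self) -> str:
        return "\t".join(
            (self.seqid, self.source, self.ftype, str(self.start),
             str(self.end), self.score, self.strand, self.frame,
             self.attributes)
        )


@dataclass(frozen=True)
class BedRow:
    """One output BED row: chrom, 0-based half-open span, geneID, count, product."""

    chrom: str
    start: int  # 0-based
    end: int    # half-open
    gene_id: str
    meth_count: int
    product: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"BED row {self.gene_id!r}: start {self.start} >= end {self.end}"
            )
        if self.meth_count < 0:
            raise FormatError(f"BED row {self.gene_id!r}: negative count")

    def to_line(self) -> str:
        return "\t".join(
            (self.chrom, str(self.start), str(self.end), self.gene_id,
             str(self.meth_count), self.product)
        )


@dataclass
class RoaryTable:
    """Roary gene_presence_absence table: gene -> strain -> geneID-or-''."""

    presence: dict[str, dict[str, str]]
    strains: tuple[str, ...]

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def is_core(self, gene_name: str) -> bool:
        """A gene is core iff present (non-empty cell) in every strain."""
        row = self.presence[gene_name]
        return all(row.get(s, "") != "" for s in self.strains)

    def label(self, gene_name: str) -> str:
        if gene_name not in self.presence:
            return "unknown"
        return "core" if self.is_core(gene_name) else "dispensable"

    def label_by_gene_id(self, gene_id: str) -> str:
        """Label a strain-level geneID by looking it up in any strain column."""
        for name, row in self.presence.items():
            for cell in row.values():
                # Roary cells may hold several ids joined by tab or semicolon
                if gene_id in _split_roary_cell(cell):
                    return "core" if self.is_core(name) else "dispensable"
        return "unknown"


def _split_roary_cell(cell: str) -> list[str]:
    if not cell:
        return []
    for sep in ("\t", ";"):
        if sep in cell:
            return [c for c in cell.split(sep) if c]
    return [cell]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[RepliconSequence]:
    """Read a (multi-)FASTA genome into RepliconSequence records.

    Sequences are uppercased; the seqid is the header token before the
    first whitespace. Empty files, duplicate seqids and non-nucleotide
    characters are hard errors naming the offending record.
    """
    path = Path(path)
    records: list[RepliconSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seqid = rec.id
        if seqid in seen:
            raise FormatError(f"{path}: duplicate seqid {seqid!r}")
        seen.add(seqid)
        records.append(RepliconSequence(seqid, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(replicons: Iterable[RepliconSequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rep in replicons:
            fh.write(f">{rep.seqid}\n")
            for i in range(0, rep.length, width):
                fh.write(rep.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (generic + annotation + modified-base dialects)
# ---------------------------------------------------------------------------

def _iter_gff_rows(path: Path):
    """Yield (line_number, 9-column list) for every body row."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_NCOLS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_GFF_NCOLS} tab-separated "
                    f"columns, found {len(cols)}"
                )
            yield lineno, cols, line


def parse_gff_attributes(attr: str) -> dict[str, str]:
    """Parse 'k1=v1;k2=v2' into a dict. Unknown tokens are ignored."""
    out: dict[str, str] = {}
    for part in attr.split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, _, v = part.partition("=")
        out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GffFeature]:
    """Read any GFF3 into generic GffFeature rows (attributes verbatim)."""
    path = Path(path)
    out: list[GffFeature] = []
    for lineno, cols, _line in _iter_gff_rows(path):
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates")
        out.append(GffFeature(cols[0], cols[1], cols[2], start, end,
                              cols[5], cols[6], cols[7], cols[8]))
    return out


def read_gff3_annotation(
    path: str | Path,
    feature_types: set[str] | None = None,
) -> list[GeneRecord]:
    """Read a GFF3 genome annotation into GeneRecords.

    ``feature_types`` defaults to {"CDS", "gene"}; when a CDS row and a
    gene row describe the same locus (same seqid/start/end), the CDS row
    wins. geneID is taken from ``ID=`` with ``locus_tag=`` fallback;
    product from ``product=`` (may be empty).
    """
    path = Path(path)
    if feature_types is None:
        feature_types = {"CDS", "gene"}
    by_locus: dict[tuple[str, int, int], tuple[str, GeneRecord]] = {}
    order: list[tuple[str, int, int]] = []
    for lineno, cols, line in _iter_gff_rows(path):
        ftype = cols[2]
        if ftype not in feature_types:
            continue
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates")
        if end < start:
            raise FormatError(
                f"{path}:{lineno}: end ({end}) < start ({start})"
            )
        attrs = parse_gff_attributes(cols[8])
        gene_id = attrs.get("ID") or attrs.get("locus_tag")
        if not gene_id:
            raise FormatError(
                f"{path}:{lineno}: no ID= or locus_tag= attribute"
            )
        rec = GeneRecord(cols[0], start, end, cols[6], gene_id,
                         attrs.get("product", ""), line)
        locus = (cols[0], start, end)
        if locus in by_locus:
            prev_type, _prev = by_locus[locus]
            # CDS preferred over gene for the same locus
            if prev_type != "CDS" and ftype == "CDS":
                by_locus[locus] = (ftype, rec)
        else:
            by_locus[locus] = (ftype, rec)
            order.append(locus)
    records = [by_locus[loc][1] for loc in order]
    seen_ids: set[str] = set()
    for rec in records:
        if rec.gene_id in seen_ids:
            raise FormatError(f"{path}: duplicate geneID {rec.gene_id!r}")
        seen_ids.add(rec.gene_id)
    return records


def read_gff3_methylation(
    path: str | Path,
    mod_types: set[str] | None = None,
) -> list[MethylationRecord]:
    """Read an SMRT Link modified-base GFF3 into MethylationRecords.

    Column 3 holds the modification type (m6A/m4C/modified_base ...),
    columns 4-5 a 1-bp interval. Rows with start != end take the midpoint
    (floored) with a logged warning — SMRT Link occasionally emits 2-bp
    contexts and rejecting them would reject real files. ``mod_types``
    optionally filters by modification type.
    """
    path = Path(path)
    out: list[MethylationRecord] = []
    for lineno, cols, _line in _iter_gff_rows(path):
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates")
        if mod_types is not None and cols[2] not in mod_types:
            continue
        if start != end:
            pos = (start + end) // 2
            logger.warning(
                "%s:%d: modified-base interval [%d,%d] is not 1 bp; "
                "using midpoint %d", path, lineno, start, end, pos)
        else:
            pos = start
        out.append(MethylationRecord(cols[0], pos, cols[6], cols[2], cols[8]))
    return out


def write_gff3(records: Sequence[GffFeature], path: str | Path) -> None:
    """Write GFF3 rows grouped by seqid (input order of first appearance),
    ascending start within each seqid."""
    seq_order: dict[str, int] = {}
    for rec in records:
        seq_order.setdefault(rec.seqid, len(seq_order))
    ordered = sorted(records,
                     key=lambda r: (seq_order[r.seqid], r.start, r.strand))
    with open(path, "w") as fh:
        fh.write(GFF_VERSION_HEADER + "\n")
        for rec in ordered:
            fh.write(rec.to_line() + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(rows: Sequence[BedRow], path: str | Path,
              header_comment: str | None = None) -> None:
    """Serialize BED rows: tab-separated, six columns, no header
    (an optional '#' comment line may carry provenance notes)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


def read_bed(path: str | Path) -> list[BedRow]:
    rows: list[BedRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            rows.append(BedRow(cols[0], int(cols[1]), int(cols[2]),
                               cols[3], int(cols[4]), cols[5]))
    return rows


# ---------------------------------------------------------------------------
# motif text file
# ---------------------------------------------------------------------------

def read_motifs(path: str | Path) -> MotifList:
    """One IUPAC motif per line; '#' comments and surrounding whitespace
    ignored. Motifs are uppercased; duplicates and invalid codes rejected."""
    motifs: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                motifs.append(line.upper())
    return MotifList(tuple(motifs))


def write_motifs(motifs: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(m + "\n")


# ---------------------------------------------------------------------------
# Roary gene_presence_absence.csv
# ---------------------------------------------------------------------------

def read_roary(path: str | Path) -> RoaryTable:
    """Read Roary's gene_presence_absence.csv (14 metadata columns, then
    one column per strain; quoted commas handled)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty Roary table")
        if len(header) <= ROARY_META_COLS:
            raise FormatError(
                f"{path}: no strain columns after the "
                f"{ROARY_META_COLS} Roary metadata columns"
            )
        strains = tuple(header[ROARY_META_COLS:])
        presence: dict[str, dict[str, str]] = {}
        for row in reader:
            if not row:
                continue
            gene_name = row[0]
            cells = row[ROARY_META_COLS:]
            presence[gene_name] = {
                strain: (cells[i] if i < len(cells) else "")
                for i, strain in enumerate(strains)
            }
    return RoaryTable(presence, strains)
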