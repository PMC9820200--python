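"""Seqid harmonization and input validation (run before any processing).

The three inputs — genome FASTA, annotation GFF3, modified-base GFF3 —
often come from different programs that format sequence identifiers
inconsistently; the most frequent issue is a pipe and an underscore used
interchangeably as separators. Normalization copies the inputs into the
output directory with an ordered list of string-replacement rules
(default: ``|`` -> ``_``) applied to every seqid, leaving the originals
untouched. The FASTA is the authority: after normalization every
annotation/methylation seqid must exist in the FASTA set, or the run
stops with the unresolved identifiers listed.

Validation then range-checks every coordinate against its replicon's
length and reports per-replicon record counts.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .formats_io import (FormatError, read_fasta, read_gff3_annotation,
                         read_gff3_methylation)

logger = logging.getLogger("mestudio")

#: default replacement rules: the pipe becomes an underscore
DEFAULT_RULES: tuple[tuple[str, str], ...] = (("|", "_"),)


class SeqidMismatchError(FormatError):
    """An annotation/methylation seqid has no FASTA counterpart."""


class CoordinateError(FormatError):
    """A coordinate lies outside its replicon."""


@dataclass
class SeqidReport:
    """What normalization saw and did."""

    fasta_seqids: set[str] = field(default_factory=set)
    annotation_seqids: set[str] = field(default_factory=set)
    methylation_seqids: set[str] = field(default_factory=set)
    mapping: dict[str, str] = field(default_factory=dict)  # old -> new
    unresolved: list[str] = field(default_factory=list)
    counts_per_replicon: dict[str, dict[str, int]] = field(default_factory=dict)


def _apply_rules(seqid: str, rules: Sequence[tuple[str, str]]) -> str:
    for old, new in rules:
        seqid = seqid.replace(old, new)
    return seqid


def _normalize_fasta(src: Path, dst: Path,
                     rules: Sequence[tuple[str, str]],
                     mapping: dict[str, str]) -> set[str]:
    seqids: set[str] = set()
    with open(src) as fin, open(dst, "w") as fout:
        for line in fin:
            if line.startswith(">"):
                header = line[1:].rstrip("\n")
                parts = header.split(None, 1)
                old = parts[0] if parts else ""
                new = _apply_rules(old, rules)
                if new != old:
                    mapping[old] = new
                rest = f" {parts[1]}" if len(parts) > 1 else ""
                fout.write(f">{new}{rest}\n")
                seqids.add(new)
            else:
                fout.write(line)
    return seqids


def _normalize_gff(src: Path, dst: Path,
                   rules: Sequence[tuple[str, str]],
                   mapping: dict[str, str]) -> set[str]:
    seqids: set[str] = set()
    with open(src) as fin, open(dst, "w") as fout:
        for line in fin:
            if not line.strip() or line.startswith("#"):
                fout.write(line)
                continue
            cols = line.rstrip("\n").split("\t")
            old = cols[0]
            new = _apply_rules(old, rules)
            if new != old:
                mapping[old] = new
            cols[0] = new
            seqids.add(new)
            fout.write("\t".join(cols) + "\n")
    return seqids


def normalize_seqids(
    fasta: str | Path,
    annotation: str | Path,
    methylation: str | Path,
    outdir: str | Path,
    replacement_rules: Sequence[tuple[str, str]] = DEFAULT_RULES,
) -> tuple[Path, Path, Path, SeqidReport]:
    """Write normalized copies of the three inputs into ``outdir``.

    Returns the three copy paths and a :class:`SeqidReport`. Originals
    are never modified. Raises :class:`SeqidMismatchError` if, after
    applying the rules, any annotation or methylation seqid is still
    absent from the FASTA seqid set.
    """
    fasta, annotation, methylation = Path(fasta), Path(annotation), Path(methylation)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = SeqidReport()

    fasta_copy = outdir / fasta.name
    ann_copy = outdir / annotation.name
    meth_copy = outdir / methylation.name
    report.fasta_seqids = _normalize_fasta(fasta, fasta_copy,
                                           replacement_rules, report.mapping)
    report.annotation_seqids = _normalize_gff(annotation, ann_copy,
                                              replacement_rules, report.mapping)
    report.methylation_seqids = _normalize_gff(methylation, meth_copy,
                                               replacement_rules, report.mapping)

    unresolved = sorted(
        (report.annotation_seqids | report.methylation_seqids)
        - report.fasta_seqids
    )
    report.unresolved = unresolved
    if unresolved:
        raise SeqidMismatchError(
            "seqid(s) absent from the FASTA after normalization: "
            + ", ".join(unresolved)
        )
    return fasta_copy, ann_copy, meth_copy, report


def validate_inputs(
    fasta: str | Path,
    annotation: str | Path,
    methylation: str | Path,
) -> SeqidReport:
    """Range-check every coordinate of normalized inputs.

    Every gene interval and methylation position must lie within its
    replicon's length. Returns per-replicon record counts; an empty
    methylation file is valid (warned, zero counts)."""
    replicons = {r.seqid: r.length for r in read_fasta(fasta)}
    genes = read_gff3_annotation(annotation)
    meth = read_gff3_methylation(methylation)

    report = SeqidReport(fasta_seqids=set(replicons))
    counts = {sid: {"genes": 0, "methylations": 0} for sid in replicons}

    for g in genes:
        if g.seqid not in replicons:
            raise SeqidMismatchError(
                f"{annotation}: gene {g.gene_id!r} on unknown seqid {g.seqid!r}"
            )
        if g.end > replicons[g.seqid]:
            raise CoordinateError(
                f"{annotation}: gene {g.gene_id!r} ends at {g.end}, beyond "
                f"replicon {g.seqid!r} length {replicons[g.seqid]}"
            )
        counts[g.seqid]["genes"] += 1
        report.annotation_seqids.add(g.seqid)

    for i, m in enumerate(meth, start=1):
        if m.seqid not in replicons:
            raise SeqidMismatchError(
                f"{methylation}: record {i} on unknown seqid {m.seqid!r}"
            )
        if m.position > replicons[m.seqid]:
            raise CoordinateError(
                f"{methylation}: record {i} position {m.position} beyond "
                f"replicon {m.seqid!r} length {replicons[m.seqid]}"
            )
        counts[m.seqid]["methylations"] += 1
        report.methylation_seqids.add(m.seqid)

    if not meth:
        logger.warning("%s: methylation file has no records", methylation)

    report.counts_per_replicon = counts
    return report
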