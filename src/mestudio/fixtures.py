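"""Synthetic, ground-truth-annotated inputs for the whole pipeline.

The generator emulates a small multi-replicon bacterial genome annotated
Prokka-style, together with an SMRT Link modified-base GFF3, a motif
file and a Roary presence/absence table — everything the pipeline reads
— with every planted motif occurrence, its feature category and its
methylation status recorded as ground truth.

Background sequence is rejection-repaired to be motif-free, so recovery
tests are exact rather than statistical: every motif match the scanner
may report is a planted one. Planting is strand-aware — a methylation
record destined for category nCDS is planted inside a gene body with the
motif oriented so the match falls on the record's (antisense) strand.

All randomness flows from the spec's seed; a given spec writes
byte-identical files on every run.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats_io import (GeneRecord, MethylationRecord, RepliconSequence,
                         write_fasta, write_motifs)
from .motif_core import IUPAC_SETS, degeneracy, expand, reverse_complement

BASES = "ACGT"

CATEGORY_ORDER = ("CDS", "nCDS", "tIG", "US")


class UnsatisfiableSpec(ValueError):
    """The requested planting cannot fit the requested genome."""


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults emulate a compact two-replicon bacterial genome carrying the
    alphaproteobacterial CcrM motif GANTC, with methylated motif hits
    planted per feature category."""

    seed: int = 1
    replicon_lengths: tuple[int, ...] = (60_000, 40_000)
    n_genes: int = 60
    gene_length: tuple[int, int] = (300, 1500)   # uniform, bp
    gap_length: tuple[int, int] = (60, 500)      # uniform, bp
    minus_strand_prob: float = 0.5
    gc: float = 0.6                              # S. meliloti-like GC
    motifs: tuple[str, ...] = ("GANTC",)
    #: methylated motif hits planted per category (CDS, nCDS, tIG, US)
    plant_counts: dict[str, int] = field(
        default_factory=lambda: {"CDS": 40, "nCDS": 25, "tIG": 10, "US": 5})
    #: additional planted-but-unmethylated hits per category
    unmethylated_per_category: int = 3
    #: stray methylation calls outside any motif occurrence
    n_noise_methylations: int = 10
    mod_type: str = "m6A"
    motif_free_background: bool = True
    n_strains: int = 2
    core_fraction: float = 0.8


@dataclass(frozen=True)
class PlantedHit:
    """Ground truth for one planted motif occurrence."""

    seqid: str
    start: int          # 1-based inclusive occurrence span
    end: int
    match_strand: str   # strand on which the scanner must report it
    motif: str
    category: str
    owner_gene_id: str
    methylated: bool
    meth_position: int  # 0 when not methylated
    meth_strand: str


@dataclass
class Fixture:
    """The generated dataset plus its ground truth, in memory."""

    spec: FixtureSpec
    replicons: list[RepliconSequence]
    genes: list[GeneRecord]
    methylations: list[MethylationRecord]
    planted: list[PlantedHit]
    paths: dict[str, Path] = field(default_factory=dict)

    def planted_counts(self) -> dict[str, int]:
        """Methylated planted hits per category (the recovery target)."""
        out = {c: 0 for c in CATEGORY_ORDER}
        for p in self.planted:
            if p.methylated:
                out[p.category] += 1
        return out


# ---------------------------------------------------------------------------
# gene layout and intergap classification (fixture-side, independent of
# feature_map: valid only for the non-overlapping layouts generated here)
# ---------------------------------------------------------------------------

def _layout_genes(spec: FixtureSpec, rng: np.random.Generator
                  ) -> list[GeneRecord]:
    total = sum(spec.replicon_lengths)
    genes: list[GeneRecord] = []
    gid = 0
    for ri, length in enumerate(spec.replicon_lengths):
        share = round(spec.n_genes * length / total)
        if ri == len(spec.replicon_lengths) - 1:
            share = spec.n_genes - (gid)
        seqid = f"contig_{ri + 1}"
        cursor = 1
        placed = 0
        while placed < share:
            gap = int(rng.integers(spec.gap_length[0], spec.gap_length[1] + 1))
            glen = int(rng.integers(spec.gene_length[0],
                                    spec.gene_length[1] + 1))
            start = cursor + gap
            end = start + glen - 1
            if end > length - spec.gap_length[0]:
                break
            gid += 1
            strand = "-" if rng.random() < spec.minus_strand_prob else "+"
            genes.append(GeneRecord(seqid, start, end, strand,
                                    f"MSFIX_{gid:05d}",
                                    f"hypothetical protein {gid}"))
            cursor = end + 1
            placed += 1
        if placed < share:
            raise UnsatisfiableSpec(
                f"replicon {seqid} ({length} bp) cannot fit {share} genes "
                f"with the requested gene/gap lengths"
            )
    return genes


def _gap_category(left: GeneRecord | None, right: GeneRecord | None
                  ) -> tuple[str, str, str]:
    """(category, strand, owner) of a gap, from its flanking genes."""
    if left is None and right is None:
        return "tIG", ".", ""
    if left is None:
        return (("US", "+", right.gene_id) if right.strand == "+"
                else ("tIG", ".", right.gene_id))
    if right is None:
        return (("US", "-", left.gene_id) if left.strand == "-"
                else ("tIG", ".", left.gene_id))
    if left.strand == right.strand:
        owner = right if left.strand == "+" else left
        return "US", owner.strand, owner.gene_id
    return "tIG", ".", f"{left.gene_id}|{right.gene_id}"


def _intergaps(spec: FixtureSpec, genes: Sequence[GeneRecord]
               ) -> list[tuple[str, int, int, str, str, str]]:
    """(seqid, start, end, category, strand, owner) for every gap."""
    out = []
    for ri, length in enumerate(spec.replicon_lengths):
        seqid = f"contig_{ri + 1}"
        rep_genes = [g for g in genes if g.seqid == seqid]
        prev: GeneRecord | None = None
        cursor = 1
        for g in rep_genes:
            if cursor <= g.start - 1:
                cat, strand, owner = _gap_category(prev, g)
                out.append((seqid, cursor, g.start - 1, cat, strand, owner))
            cursor = g.end + 1
            prev = g
        if cursor <= length:
            cat, strand, owner = _gap_category(prev, None)
            out.append((seqid, cursor, length, cat, strand, owner))
    return out


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def _concretize(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        sorted(IUPAC_SETS[c])[int(rng.integers(len(IUPAC_SETS[c])))]
        for c in motif
    )


def _meth_offset(motif: str, mod_type: str = "m6A") -> int:
    """Offset of the methylated base within a plus-strand occurrence:
    the first position compatible with the modified base (A for m6A,
    C for m4C/m5C), else the middle of the motif."""
    base = "C" if mod_type.startswith(("m4", "m5")) else "A"
    for i, c in enumerate(motif):
        if base in IUPAC_SETS[c]:
            return i
    return len(motif) // 2


def _plan_plantings(spec: FixtureSpec, genes, gaps, rng
                    ) -> list[PlantedHit]:
    """Choose non-overlapping loci for every planted hit."""
    targets: dict[str, list[tuple[str, int, int, str, str]]] = {
        "CDS": [], "nCDS": [], "tIG": [], "US": []}
    for g in genes:
        targets["CDS"].append((g.seqid, g.start, g.end, g.strand, g.gene_id))
        targets["nCDS"].append((g.seqid, g.start, g.end, g.strand, g.gene_id))
    for seqid, s, e, cat, strand, owner in gaps:
        if cat in ("tIG", "US"):
            targets[cat].append((seqid, s, e, strand, owner))

    occupied: dict[str, set[int]] = {}
    planted: list[PlantedHit] = []
    motif_cycle = list(spec.motifs)

    def plant_one(category: str, methylated: bool, k: int) -> None:
        motif = motif_cycle[k % len(motif_cycle)]
        m = len(motif)
        pool = targets[category]
        if not pool:
            raise UnsatisfiableSpec(
                f"no {category} interval available to plant into")
        for _attempt in range(500):
            seqid, s, e, istrand, owner = pool[int(rng.integers(len(pool)))]
            if e - s + 1 < m + 2:
                continue
            start = int(rng.integers(s, e - m + 2))
            span = range(start, start + m)
            occ = occupied.setdefault(seqid, set())
            if any(p in occ for p in span):
                continue
            # decide the methylation strand the category requires
            if category == "CDS":
                meth_strand = istrand
            elif category == "nCDS":
                meth_strand = "-" if istrand == "+" else "+"
            elif category == "US":
                meth_strand = istrand
            else:
                meth_strand = "+" if rng.random() < 0.5 else "-"
            occ.update(span)
            off = _meth_offset(motif, spec.mod_type)
            if meth_strand == "+":
                mpos = start + off
            else:
                mpos = start + (m - 1 - off)
            planted.append(PlantedHit(
                seqid, start, start + m - 1, meth_strand, motif, category,
                owner, methylated, mpos if methylated else 0, meth_strand))
            return
        raise UnsatisfiableSpec(
            f"could not place a {category} planting after 500 attempts")

    k = 0
    for category in CATEGORY_ORDER:
        for _ in range(spec.plant_counts.get(category, 0)):
            plant_one(category, True, k)
            k += 1
        for _ in range(spec.unmethylated_per_category):
            plant_one(category, False, k)
            k += 1
    return planted


def _find_all(seq: str, word: str) -> list[int]:
    out = []
    i = seq.find(word)
    while i != -1:
        out.append(i)
        i = seq.find(word, i + 1)
    return out


def _build_sequences(spec: FixtureSpec, planted: Sequence[PlantedHit],
                     rng: np.random.Generator) -> list[RepliconSequence]:
    probs = np.array([(1 - spec.gc) / 2, spec.gc / 2,
                      spec.gc / 2, (1 - spec.gc) / 2])
    replicons: list[RepliconSequence] = []
    planted_by_rep: dict[str, list[PlantedHit]] = {}
    for p in planted:
        planted_by_rep.setdefault(p.seqid, []).append(p)

    # every concrete word whose presence would be an unplanted match
    words: set[str] = set()
    for motif in spec.motifs:
        if degeneracy(motif) <= 4096:
            words.update(expand(motif))
            words.update(expand(reverse_complement(motif)))

    for ri, length in enumerate(spec.replicon_lengths):
        seqid = f"contig_{ri + 1}"
        arr = rng.choice(list(BASES), size=length, p=probs)
        protected: set[int] = set()
        for p in planted_by_rep.get(seqid, ()):
            word = _concretize(p.motif, rng)
            if p.match_strand == "-":
                word = reverse_complement(word)
            # keep a methylatable base at the methylated position
            if p.methylated:
                off = p.meth_position - p.start
                want = "A" if p.meth_strand == "+" else "T"
                if spec.mod_type.startswith("m4"):
                    want = "C" if p.meth_strand == "+" else "G"
                cands = [w for w in
                         (expand(p.motif) if p.match_strand == "+"
                          else expand(reverse_complement(p.motif)))
                         if w[off] == want]
                if cands:
                    word = cands[int(rng.integers(len(cands)))]
            for j, ch in enumerate(word):
                arr[p.start - 1 + j] = ch
            protected.update(range(p.start - 1, p.end))
        seq = "".join(arr)
        if spec.motif_free_background and words:
            seq = _repair(seq, words, protected, rng)
        replicons.append(RepliconSequence(seqid, seq))
    return replicons


def _repair(seq: str, words: set[str], protected: set[int],
            rng: np.random.Generator, max_rounds: int = 60) -> str:
    """Mutate background bases until no unplanted motif word remains."""
    arr = list(seq)
    for _ in range(max_rounds):
        dirty = False
        for word in sorted(words):
            for i in _find_all("".join(arr), word):
                span = [p for p in range(i, i + len(word))
                        if p not in protected]
                if not span:  # fully inside a planted occurrence: fine
                    continue
                dirty = True
                p = span[int(rng.integers(len(span)))]
                choices = [b for b in BASES if b != arr[p]]
                arr[p] = choices[int(rng.integers(3))]
        if not dirty:
            return "".join(arr)
    raise UnsatisfiableSpec("could not clear background motif matches")


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _write_annotation(genes: Sequence[GeneRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            # paired gene + CDS rows, Prokka-style; the reader must
            # de-duplicate to one record per locus
            fh.write("\t".join((g.seqid, "fixture", "gene", str(g.start),
                                str(g.end), ".", g.strand, ".",
                                f"ID={g.gene_id}_gene")) + "\n")
            fh.write("\t".join((g.seqid, "fixture", "CDS", str(g.start),
                                str(g.end), ".", g.strand, "0",
                                f"ID={g.gene_id};product={g.product}"))
                     + "\n")


def _write_methylation(meth: Sequence[MethylationRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in meth:
            fh.write("\t".join((m.seqid, "kinModCall", m.mod_type,
                                str(m.position), str(m.position), "40",
                                m.strand, ".", m.attributes)) + "\n")


def _write_roary(spec: FixtureSpec, genes: Sequence[GeneRecord],
                 path: Path, rng: np.random.Generator) -> dict[str, str]:
    meta = ["Gene", "Non-unique Gene name", "Annotation", "No. isolates",
            "No. sequences", "Avg sequences per isolate", "Genome Fragment",
            "Order within Fragment", "Accessory Fragment",
            "Accessory Order with Fragment", "QC", "Min group size nuc",
            "Max group size nuc", "Avg group size nuc"]
    strains = [f"strain_{chr(ord('A') + i)}" for i in range(spec.n_strains)]
    labels: dict[str, str] = {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
        writer.writerow(meta + strains)
        for g in genes:
            core = rng.random() < spec.core_fraction
            labels[g.gene_id] = "core" if core else "dispensable"
            cells = [g.gene_id]
            for s in strains[1:]:
                cells.append(f"{s}_{g.gene_id}" if core else "")
            n_present = sum(1 for c in cells if c)
            writer.writerow(
                [g.gene_id, "", g.product, str(n_present), str(n_present),
                 "1.0", "1", "1", "", "", "", "0", "0", "0"] + cells)
    return labels


def _write_ground_truth(planted: Sequence[PlantedHit], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("seqid\tstart\tend\tmatch_strand\tmotif\tcategory\towner"
                 "\tmethylated\tmeth_position\tmeth_strand\n")
        for p in planted:
            fh.write(f"{p.seqid}\t{p.start}\t{p.end}\t{p.match_strand}\t"
                     f"{p.motif}\t{p.category}\t{p.owner_gene_id}\t"
                     f"{int(p.methylated)}\t{p.meth_position}\t"
                     f"{p.meth_strand}\n")


def generate(spec: FixtureSpec, outdir: str | Path | None = None) -> Fixture:
    """Generate the full synthetic dataset; write files when ``outdir``
    is given. Deterministic for a given spec (byte-identical files).
    Raises :class:`UnsatisfiableSpec` before writing anything when the
    requested planting cannot fit."""
    rng = np.random.default_rng(spec.seed)
    genes = _layout_genes(spec, rng)
    gaps = _intergaps(spec, genes)
    planted = _plan_plantings(spec, genes, gaps, rng)
    replicons = _build_sequences(spec, planted, rng)

    meth: list[MethylationRecord] = []
    for p in planted:
        if p.methylated:
            meth.append(MethylationRecord(
                p.seqid, p.meth_position, p.meth_strand, spec.mod_type,
                f"coverage={int(rng.integers(40, 250))};"
                f"context={p.motif};IPDRatio="
                f"{rng.uniform(2.0, 7.0):.2f}"))
    # stray calls outside any motif occurrence (background is motif-free,
    # so these can never enter a motif's crossed output)
    occupied: dict[str, set[int]] = {}
    for p in planted:
        occupied.setdefault(p.seqid, set()).update(range(p.start, p.end + 1))
    lengths = {r.seqid: r.length for r in replicons}
    for _ in range(spec.n_noise_methylations):
        for _attempt in range(200):
            rep = replicons[int(rng.integers(len(replicons)))]
            pos = int(rng.integers(1, lengths[rep.seqid] + 1))
            if pos not in occupied.get(rep.seqid, set()):
                meth.append(MethylationRecord(
                    rep.seqid, pos,
                    "+" if rng.random() < 0.5 else "-", spec.mod_type,
                    f"coverage={int(rng.integers(40, 250))};"
                    f"IPDRatio={rng.uniform(2.0, 7.0):.2f}"))
                break
    meth.sort(key=lambda m: (m.seqid, m.position, m.strand))

    fixture = Fixture(spec, replicons, genes, meth, planted)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fasta",
            "annotation": outdir / "annotation.gff3",
            "methylation": outdir / "methylation.gff3",
            "motifs": outdir / "motifs.txt",
            "roary": outdir / "gene_presence_absence.csv",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        write_fasta(replicons, paths["fasta"])
        _write_annotation(genes, paths["annotation"])
        _write_methylation(meth, paths["methylation"])
        write_motifs(spec.motifs, paths["motifs"])
        _write_roary(spec, genes, paths["roary"], rng)
        _write_ground_truth(planted, paths["ground_truth"])
        fixture.paths = paths
    return fixture
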