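"""IUPAC-degenerate motif matching on both strands of each replicon.

The matcher is a plain naive scanner with early mismatch exit: every
window of length m on the plus strand is tested against the pattern
(a hit is a "+" match) and against the pattern's reverse complement
(a "-" match), so all coordinates are reported on the plus strand.
Worst-case time is O(m * (n - m + 1)) per strand, plus a term that grows
with the number and breadth of ambiguity codes in the motif.

Palindromic motifs (pattern == its own IUPAC reverse complement, e.g.
GANTC, the CcrM target) hit the same locus on both strands; both hits are
reported, one per strand, because downstream crossing is strand-aware and
collapsing here would erase the CDS/nCDS distinction.

An N in the *genome* matches only the motif code N, never A/C/G/T codes:
methylation cannot be evidenced on an unknown base, and this keeps
assembly gaps from inflating match counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

from .formats_io import MotifList, RepliconSequence

#: IUPAC nucleotide code -> set of concrete bases it stands for
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: IUPAC complement (A<->T, C<->G, R<->Y, K<->M, B<->V, D<->H; S,W,N self)
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}


class MotifError(ValueError):
    """Raised for invalid IUPAC motif strings."""


def _check_pattern(pattern: str) -> None:
    bad = set(pattern) - set(IUPAC_SETS)
    if bad:
        raise MotifError(
            f"motif {pattern!r}: invalid IUPAC code(s) {sorted(bad)!r}"
        )


def iupac_matches(code: str, base: str) -> bool:
    """True iff genome ``base`` (A/C/G/T/N) satisfies motif ``code``.

    Genome N matches only code N (see module docstring).
    """
    if code not in IUPAC_SETS:
        raise MotifError(f"invalid IUPAC code {code!r}")
    if base == "N":
        return code == "N"
    return base in IUPAC_SETS[code]


def reverse_complement(pattern: str) -> str:
    """IUPAC-aware reverse complement of a motif string."""
    _check_pattern(pattern)
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern))


def degeneracy(pattern: str) -> int:
    """Number of concrete A/C/G/T words the pattern stands for."""
    _check_pattern(pattern)
    d = 1
    for c in pattern:
        d *= len(IUPAC_SETS[c])
    return d


def expand(pattern: str) -> list[str]:
    """All concrete words of the pattern (the brute-force oracle's input)."""
    _check_pattern(pattern)
    words = [""]
    for c in pattern:
        words = [w + b for w in words for b in sorted(IUPAC_SETS[c])]
    return words


@dataclass(frozen=True)
class Motif:
    """A validated IUPAC motif with its derived properties."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise MotifError("empty motif")
        _check_pattern(self.pattern)

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.pattern)

    @property
    def is_palindromic(self) -> bool:
        return self.pattern == reverse_complement(self.pattern)


@dataclass(frozen=True, order=True)
class MotifMatch:
    """One motif occurrence in plus-strand coordinates (1-based inclusive)."""

    seqid: str
    start: int
    end: int
    strand: str
    motif: str


@lru_cache(maxsize=256)
def _match_sets(pattern: str) -> tuple[frozenset[str], ...]:
    # genome N only satisfies code N
    return tuple(
        IUPAC_SETS[c] | frozenset("N") if c == "N" else IUPAC_SETS[c]
        for c in pattern
    )


def _scan_one_strand(seq: str, pattern: str) -> list[int]:
    """0-based start offsets where ``pattern`` matches ``seq`` (naive scan,
    early exit on first mismatching position)."""
    sets = _match_sets(pattern)
    m = len(pattern)
    n = len(seq)
    if m == 0 or m > n:
        return []
    # degeneracy-1 patterns reduce to exact substring search
    if all(len(s) == 1 for s in sets):
        word = "".join(next(iter(s)) for s in sets)
        hits: list[int] = []
        i = seq.find(word)
        while i != -1:
            hits.append(i)
            i = seq.find(word, i + 1)
        return hits
    hits = []
    for i in range(n - m + 1):
        for j in range(m):
            if seq[i + j] not in sets[j]:
                break
        else:
            hits.append(i)
    return hits


def scan_replicon(replicon: RepliconSequence,
                  motif: Motif | str) -> list[MotifMatch]:
    """All occurrences of ``motif`` on both strands of one replicon.

    Matches are reported in plus-strand coordinates, sorted by start then
    strand ("+" before "-"). A motif longer than the replicon yields an
    empty result. Overlapping matches are all reported; there is no
    wraparound across the replicon origin.
    """
    if isinstance(motif, str):
        motif = Motif(motif)
    seq = replicon.sequence
    fwd = _scan_one_strand(seq, motif.pattern)
    rc = reverse_complement(motif.pattern)
    rev = _scan_one_strand(seq, rc)
    m = motif.length
    matches = [
        MotifMatch(replicon.seqid, i + 1, i + m, "+", motif.pattern)
        for i in fwd
    ] + [
        MotifMatch(replicon.seqid, i + 1, i + m, "-", motif.pattern)
        for i in rev
    ]
    matches.sort(key=lambda x: (x.start, x.strand))
    return matches


def scan_genome(
    replicons: Iterable[RepliconSequence],
    motifs: MotifList | Iterable[str],
) -> dict[str, list[MotifMatch]]:
    """Per-motif concatenation of :func:`scan_replicon` over all replicons,
    in FASTA replicon order."""
    replicons = list(replicons)
    result: dict[str, list[MotifMatch]] = {}
    for pattern in motifs:
        motif = Motif(pattern if isinstance(pattern, str) else pattern)
        hits: list[MotifMatch] = []
        for rep in replicons:
            hits.extend(scan_replicon(rep, motif))
        result[motif.pattern] = hits
    return result


# ---------------------------------------------------------------------------
# serialization of match sets (intermediate GFF3, column 3 = "motif_match")
# ---------------------------------------------------------------------------

def matches_to_gff(matches: Iterable[MotifMatch]):
    from .formats_io import GffFeature
    return [
        GffFeature(m.seqid, "mestudio", "motif_match", m.start, m.end,
                   ".", m.strand, ".", f"motif={m.motif}")
        for m in matches
    ]


def gff_to_matches(features) -> list[MotifMatch]:
    from .formats_io import parse_gff_attributes
    out = []
    for f in features:
        attrs = parse_gff_attributes(f.attributes)
        out.append(MotifMatch(f.seqid, f.start, f.end, f.strand,
                              attrs.get("motif", "")))
    return out
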