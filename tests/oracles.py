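"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's own scanning/crossing code paths:
the motif oracle expands a degenerate motif into every concrete word and
substring-searches each word on both strands; the crossing oracle is a
plain triple loop over (record, match, interval).
"""

from __future__ import annotations

from mestudio.motif_core import expand, reverse_complement

# NOTE: expand/reverse_complement are small table lookups shared with the
# implementation; the search itself (str.find per concrete word) is
# independent of the naive window scanner.


def oracle_scan(seq: str, motif: str) -> list[tuple[int, int, str]]:
    """All (start, end, strand) occurrences, 1-based inclusive, sorted.

    A genome N never satisfies a concrete word, matching the rule that an
    unknown base cannot evidence methylation; words containing N can only
    arise from motif code N, and those are searched literally.
    """
    hits: set[tuple[int, int, str]] = set()
    m = len(motif)

    def words_for(pattern: str) -> set[str]:
        out = set()
        for w in expand(pattern):
            out.add(w)
        # motif code N also matches genome N at that position
        n_positions = [i for i, c in enumerate(pattern) if c == "N"]
        if n_positions:
            # enumerate N->N substitutions on top of each word
            base_words = list(out)
            for w in base_words:
                for mask in range(1, 2 ** len(n_positions)):
                    chars = list(w)
                    for b, i in enumerate(n_positions):
                        if mask >> b & 1:
                            chars[i] = "N"
                    out.add("".join(chars))
        return out

    for strand, pattern in (("+", motif), ("-", reverse_complement(motif))):
        for word in words_for(pattern):
            i = seq.find(word)
            while i != -1:
                hits.add((i + 1, i + m, strand))
                i = seq.find(word, i + 1)
    return sorted(hits)


def oracle_cross(records, matches_by_motif, features):
    """Triple-loop crossing: motif -> category -> count of records.

    Mirrors the documented semantics directly: a record counts for motif
    M iff some M match on the record's strand contains its position; the
    category is CDS/nCDS inside a gene body (strand-accordant or not),
    else US if a same-strand US interval contains it, else tIG.
    """
    def strand_ok(a, b):
        return a == "." or b == "." or a == b

    out = {}
    for motif, matches in matches_by_motif.items():
        counts = {"CDS": 0, "nCDS": 0, "tIG": 0, "US": 0}
        for rec in records:
            inside = False
            for m in matches:
                if (m.seqid == rec.seqid and m.start <= rec.position <= m.end
                        and strand_ok(rec.strand, m.strand)):
                    inside = True
                    break
            if not inside:
                continue
            bodies = [f for f in features["CDS"]
                      if f.seqid == rec.seqid
                      and f.start <= rec.position <= f.end]
            if bodies:
                for body in bodies:
                    if strand_ok(rec.strand, body.strand):
                        counts["CDS"] += 1
                    else:
                        counts["nCDS"] += 1
                continue
            in_us = any(
                f.seqid == rec.seqid and f.start <= rec.position <= f.end
                and strand_ok(rec.strand, f.strand)
                for f in features["US"])
            counts["US" if in_us else "tIG"] += 1
        out[motif] = counts
    return out
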