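import random
from collections import Counter
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from mestudio.crosser_stats import (cross, crossed_to_gff, make_bed,
                                    make_chrom, summarize)
from mestudio.feature_map import derive_features
from mestudio.formats_io import (GeneRecord, MethylationRecord,
                                 RepliconSequence, read_roary)
from mestudio.motif_core import MotifMatch, scan_genome
from oracles import oracle_cross


def simple_setup(gene_strand="+"):
    replicons = [RepliconSequence("c1", "A" * 100)]
    genes = [GeneRecord("c1", 10, 30, gene_strand, "g1", "prot1"),
             GeneRecord("c1", 50, 80, "+", "g2", "prot2")]
    features = derive_features(replicons, genes)
    matches = {"GANTC": [MotifMatch("c1", 13, 17, "+", "GANTC"),
                         MotifMatch("c1", 13, 17, "-", "GANTC")]}
    return replicons, genes, features, matches


def test_record_in_sense_gene_is_cds():
    _, genes, features, matches = simple_setup("+")
    rec = MethylationRecord("c1", 15, "+", "m6A", "coverage=120")
    out = cross([rec], matches, features, genes)
    assert len(out["GANTC"]["CDS"]) == 1
    r = out["GANTC"]["CDS"][0]
    assert (r.gene_id, r.product, r.category) == ("g1", "prot1", "CDS")


def test_same_record_antisense_gene_is_ncds():
    _, genes, features, matches = simple_setup("-")
    rec = MethylationRecord("c1", 15, "+", "m6A", "")
    out = cross([rec], matches, features, genes)
    assert len(out["GANTC"]["nCDS"]) == 1
    assert out["GANTC"]["CDS"] == []


def test_record_outside_any_match_is_dropped():
    _, genes, features, matches = simple_setup()
    rec = MethylationRecord("c1", 40, "+", "m6A", "")
    out = cross([rec], matches, features, genes)
    assert all(not v for v in out["GANTC"].values())


def test_strand_gating_against_match():
    """A record only enters a motif's output via a match on its strand;
    '.' records are matched permissively."""
    _, genes, features, _ = simple_setup()
    matches = {"GCCAGG": [MotifMatch("c1", 13, 18, "-", "GCCAGG")]}
    plus = MethylationRecord("c1", 15, "+", "m6A", "")
    minus = MethylationRecord("c1", 15, "-", "m6A", "")
    dot = MethylationRecord("c1", 15, ".", "m6A", "")
    out = cross([plus, minus, dot], matches, features, genes)
    total = sum(len(v) for v in out["GCCAGG"].values())
    assert total == 2  # minus and dot pass, plus does not


def test_unknown_seqid_is_hard_error():
    _, genes, features, matches = simple_setup()
    rec = MethylationRecord("cX", 15, "+", "m6A", "")
    with pytest.raises(ValueError, match="unknown seqid"):
        cross([rec], matches, features, genes)


def test_overlapping_genes_credit_every_gene():
    replicons = [RepliconSequence("c1", "A" * 100)]
    genes = [GeneRecord("c1", 10, 60, "+", "g1", "p1"),
             GeneRecord("c1", 40, 90, "+", "g2", "p2")]
    features = derive_features(replicons, genes)
    matches = {"M": [MotifMatch("c1", 48, 52, "+", "M")]}
    rec = MethylationRecord("c1", 50, "+", "m6A", "")
    out = cross([rec], matches, features, genes)
    assert sorted(r.gene_id for r in out["M"]["CDS"]) == ["g1", "g2"]
    # totals count records, not record-gene pairs
    summary = summarize(out, genes, features)
    assert summary.per_category["CDS"].n_methylated_sites == 1


def test_planted_category_counts_recovered(default_fixture):
    fx = default_fixture
    matches = scan_genome(fx.replicons, fx.spec.motifs)
    features = derive_features(fx.replicons, fx.genes)
    out = cross(fx.methylations, matches, features, fx.genes)
    counts = {c: len(v) for c, v in out["GANTC"].items()}
    assert counts == fx.planted_counts()


def test_cross_agrees_with_triple_loop_oracle(small_fixture):
    fx = small_fixture
    matches = scan_genome(fx.replicons, fx.spec.motifs)
    features = derive_features(fx.replicons, fx.genes)
    got = cross(fx.methylations, matches, features, fx.genes)
    expected = oracle_cross(fx.methylations, matches, features)
    for motif in matches:
        assert {c: len(v) for c, v in got[motif].items()} == expected[motif]


def test_strand_flip_swaps_cds_and_ncds(default_fixture):
    fx = default_fixture
    matches = scan_genome(fx.replicons, fx.spec.motifs)
    features = derive_features(fx.replicons, fx.genes)
    before = cross(fx.methylations, matches, features, fx.genes)
    flip = {"+": "-", "-": "+", ".": "."}
    flipped = [replace(m, strand=flip[m.strand]) for m in fx.methylations]
    after = cross(flipped, matches, features, fx.genes)
    for motif in matches:
        assert len(after[motif]["CDS"]) == len(before[motif]["nCDS"])
        assert len(after[motif]["nCDS"]) == len(before[motif]["CDS"])
        # intergenic records stay intergenic (US may migrate to tIG)
        assert (len(after[motif]["tIG"]) + len(after[motif]["US"])
                == len(before[motif]["tIG"]) + len(before[motif]["US"]))


def test_conservation_bound(default_fixture):
    """Sum over categories equals the number of methylation records lying
    inside any match of the motif (every such record is categorizable)."""
    fx = default_fixture
    matches = scan_genome(fx.replicons, fx.spec.motifs)
    features = derive_features(fx.replicons, fx.genes)
    out = cross(fx.methylations, matches, features, fx.genes)
    for motif, hits in matches.items():
        inside = 0
        for rec in fx.methylations:
            if any(h.seqid == rec.seqid and h.start <= rec.position <= h.end
                   and (rec.strand == "." or rec.strand == h.strand)
                   for h in hits):
                inside += 1
        assert sum(len(v) for v in out[motif].values()) == inside


# ----------------------------------------------------------- regroupings

def test_make_chrom_conserves_row_multisets(default_fixture):
    fx = default_fixture
    matches = scan_genome(fx.replicons, fx.spec.motifs)
    features = derive_features(fx.replicons, fx.genes)
    crossed = cross(fx.methylations, matches, features, fx.genes)
    seqids = [r.seqid for r in fx.replicons]
    by_chrom = make_chrom(crossed, seqids)
    assert set(by_chrom) == set(seqids)
    chrom_rows = Counter(r.to_line()
                         for rows in by_chrom.values() for r in rows)
    feature_rows = Counter(
        r.to_line()
        for per_cat in crossed.values()
        for recs in per_cat.values()
        for r in crossed_to_gff(recs))
    assert chrom_rows == feature_rows


def test_make_chrom_emits_empty_replicons():
    out = make_chrom({"GANTC": {"CDS": [], "nCDS": [], "tIG": [], "US": []}},
                     ["c1", "c2"])
    assert out == {"c1": [], "c2": []}


# ------------------------------------------------------------------- BED

def test_bed_counts_and_coordinates(default_fixture):
    fx = default_fixture
    matches = scan_genome(fx.replicons, fx.spec.motifs)
    features = derive_features(fx.replicons, fx.genes)
    crossed = cross(fx.methylations, matches, features, fx.genes)
    beds = make_bed(crossed, fx.genes, features)
    # zero-count genes are emitted: CDS table is a complete gene table
    assert len(beds["CDS"]) == len(fx.genes)
    by_id = {g.gene_id: g for g in fx.genes}
    for row in beds["CDS"]:
        gene = by_id[row.gene_id]
        assert (row.start, row.end) == (gene.start - 1, gene.end)
    # conservation: per-category sums equal crossed record counts
    for cat in ("CDS", "nCDS", "US", "tIG"):
        total = sum(len(per_cat[cat]) for per_cat in crossed.values())
        assert sum(r.meth_count for r in beds[cat]) == total


def test_bed_only_methylated_filter(default_fixture):
    fx = default_fixture
    matches = scan_genome(fx.replicons, fx.spec.motifs)
    features = derive_features(fx.replicons, fx.genes)
    crossed = cross(fx.methylations, matches, features, fx.genes)
    beds = make_bed(crossed, fx.genes, features, only_methylated=True)
    assert all(r.meth_count > 0 for rows in beds.values() for r in rows)


# --------------------------------------------------------------- summary

def test_summarize_top_gene_and_ties():
    genes = [GeneRecord("c1", 1, 10, "+", "gA", "pA"),
             GeneRecord("c1", 20, 30, "+", "gB", "pB")]
    from mestudio.crosser_stats import CrossedRecord
    recs = ([CrossedRecord("c1", i, "+", "m6A", "", "M", "CDS", "gB", "pB")
             for i in range(20, 23)]
            + [CrossedRecord("c1", i, "+", "m6A", "", "M", "CDS", "gA", "pA")
               for i in range(1, 4)])
    crossed = {"M": {"CDS": recs, "nCDS": [], "tIG": [], "US": []}}
    s = summarize(crossed, genes)
    cds = s.per_category["CDS"]
    assert cds.n_methylated_genes == 2
    # tie (3 vs 3): lexicographically smallest geneID wins
    assert cds.top_gene_id == "gA"
    assert cds.top_gene_product == "pA"


def test_summarize_empty_is_zeros():
    s = summarize({}, [], {"CDS": [], "nCDS": [], "tIG": [], "US": []})
    for cat, stats in s.per_category.items():
        assert stats.n_methylated_sites == 0
        assert stats.top_gene_id == ""


def test_summarize_roary_labels(default_fixture, caplog):
    fx = default_fixture
    matches = scan_genome(fx.replicons, fx.spec.motifs)
    features = derive_features(fx.replicons, fx.genes)
    crossed = cross(fx.methylations, matches, features, fx.genes)
    table = read_roary(fx.paths["roary"])
    s = summarize(crossed, fx.genes, features, table)
    assert s.gene_labels
    assert set(s.gene_labels.values()) <= {"core", "dispensable", "unknown"}
    # labels agree with the table itself
    for gid, label in s.gene_labels.items():
        assert table.label_by_gene_id(gid) == label
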