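import pytest

from mestudio.formats_io import (BedRow, FormatError, GffFeature,
                                 read_bed, read_fasta, read_gff3,
                                 read_gff3_annotation,
                                 read_gff3_methylation, read_motifs,
                                 read_roary, write_bed, write_gff3,
                                 write_motifs)


# --------------------------------------------------------------------- FASTA

def test_read_fasta_normalizes_and_splits_headers(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">c1 some description\nacgt\n")
    recs = read_fasta(p)
    assert len(recs) == 1
    assert recs[0].seqid == "c1"
    assert recs[0].sequence == "ACGT"
    assert recs[0].length == 4


@pytest.mark.parametrize("content, msg", [
    (">c1\nAC\n>c1\nGT\n", "duplicate"),
    ("", "no FASTA records"),
    (">c1\nACXT\n", "non-nucleotide"),
])
def test_read_fasta_rejects_malformed(tmp_path, content, msg):
    p = tmp_path / "g.fa"
    p.write_text(content)
    with pytest.raises(FormatError, match=msg):
        read_fasta(p)


def test_read_fasta_recovers_replicon_lengths(tmp_path, default_fixture):
    recs = read_fasta(default_fixture.paths["fasta"])
    lengths = [r.length for r in recs]
    assert tuple(lengths) == default_fixture.spec.replicon_lengths


# ----------------------------------------------------------------- GFF3 in

def test_annotation_row_maps_fields(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text("##gff-version 3\n"
                 "c1\tProkka\tCDS\t10\t30\t.\t+\t0\t"
                 "ID=g1;product=hypothetical protein\n")
    (rec,) = read_gff3_annotation(p)
    assert (rec.seqid, rec.start, rec.end, rec.strand) == ("c1", 10, 30, "+")
    assert rec.gene_id == "g1"
    assert rec.product == "hypothetical protein"


def test_annotation_inverted_interval_is_error(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text("c1\tx\tCDS\t10\t9\t.\t+\t0\tID=g1\n")
    with pytest.raises(FormatError, match="end"):
        read_gff3_annotation(p)


def test_annotation_bad_column_count_names_line(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text("c1\tx\tCDS\t10\t30\n")
    with pytest.raises(FormatError, match=":1:"):
        read_gff3_annotation(p)


def test_paired_gene_and_cds_rows_deduplicate_to_cds(default_fixture):
    """The fixture writes a gene row and a CDS row per locus; the reader
    must keep exactly one record per locus, preferring the CDS."""
    recs = read_gff3_annotation(default_fixture.paths["annotation"])
    assert len(recs) == len(default_fixture.genes)
    # CDS preferred: IDs come from the CDS rows (no _gene suffix)
    assert all(not r.gene_id.endswith("_gene") for r in recs)


def test_locus_tag_fallback_for_gene_id(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text("c1\tx\tCDS\t5\t10\t.\t-\t0\tlocus_tag=LT_1\n")
    (rec,) = read_gff3_annotation(p)
    assert rec.gene_id == "LT_1"


def test_methylation_reader_maps_and_filters(tmp_path):
    p = tmp_path / "m.gff3"
    p.write_text("c1\tkinModCall\tm6A\t15\t15\t40\t+\t.\tcoverage=120\n"
                 "c1\tkinModCall\tm4C\t20\t20\t33\t-\t.\tcoverage=80\n")
    recs = read_gff3_methylation(p)
    assert [(r.position, r.strand, r.mod_type) for r in recs] == \
        [(15, "+", "m6A"), (20, "-", "m4C")]
    assert recs[0].attributes == "coverage=120"
    assert read_gff3_methylation(p, mod_types={"m4C"})[0].mod_type == "m4C"
    assert read_gff3_methylation(p, mod_types={"m5C"}) == []


def test_methylation_two_bp_interval_uses_midpoint(tmp_path, caplog):
    p = tmp_path / "m.gff3"
    p.write_text("c1\tkinModCall\tm6A\t15\t16\t40\t+\t.\tcoverage=9\n")
    (rec,) = read_gff3_methylation(p)
    assert rec.position == 15
    assert any("midpoint" in r.message for r in caplog.records)


def test_methylation_fixture_counts(tmp_path):
    lines = ["##gff-version 3"]
    for i in range(50):
        lines.append(f"c1\tkinModCall\tm6A\t{i + 1}\t{i + 1}\t40\t+\t.\tx=1")
    for i in range(30):
        lines.append(f"c1\tkinModCall\tm4C\t{i + 100}\t{i + 100}\t40\t-\t.\tx=1")
    p = tmp_path / "m.gff3"
    p.write_text("\n".join(lines) + "\n")
    assert len(read_gff3_methylation(p, mod_types={"m6A"})) == 50
    assert len(read_gff3_methylation(p)) == 80


# ---------------------------------------------------------------- GFF3 out

def test_write_gff3_round_trip_and_sorting(tmp_path):
    rows = [
        GffFeature("c2", "s", "motif_match", 7, 11, ".", "+", ".", "motif=GANTC"),
        GffFeature("c1", "s", "motif_match", 40, 44, ".", "-", ".", "motif=GANTC"),
        GffFeature("c1", "s", "motif_match", 3, 7, ".", "+", ".", "motif=GANTC"),
    ]
    p = tmp_path / "out.gff3"
    write_gff3(rows, p)
    text = p.read_text()
    assert text.startswith("##gff-version 3\n")
    back = read_gff3(p)
    # grouped by seqid (first-appearance order c2, c1), ascending start
    assert [(r.seqid, r.start) for r in back] == [("c2", 7), ("c1", 3),
                                                 ("c1", 40)]
    assert set(back) == set(rows)


def test_gff3_round_trip_randomized(tmp_path):
    """read(write(x)) preserves every field for random record sets."""
    import random
    rng = random.Random(77)
    rows = []
    for i in range(100):
        start = rng.randint(1, 5000)
        rows.append(GffFeature(
            f"c{rng.randint(1, 3)}", "src", rng.choice(["m6A", "m4C"]),
            start, start + rng.randint(0, 20), str(rng.randint(0, 60)),
            rng.choice("+-."), ".",
            f"coverage={rng.randint(1, 300)};IPDRatio={i}"))
    p = tmp_path / "rt.gff3"
    write_gff3(rows, p)
    from collections import Counter
    assert Counter(read_gff3(p)) == Counter(rows)


def test_write_gff3_empty_is_header_only(tmp_path):
    p = tmp_path / "empty.gff3"
    write_gff3([], p)
    assert p.read_text() == "##gff-version 3\n"


# --------------------------------------------------------------------- BED

def test_bed_serialization_and_coordinate_law(tmp_path):
    row = BedRow("c1", 9, 30, "g1", 4, "hypothetical protein")
    p = tmp_path / "f.bed"
    write_bed([row], p)
    assert p.read_text() == "c1\t9\t30\tg1\t4\thypothetical protein\n"
    (back,) = read_bed(p)
    assert back == row
    # GFF3 10..30 -> BED [9, 30): widths agree
    assert back.end - back.start == 30 - 10 + 1


def test_bed_empty_and_invalid(tmp_path):
    p = tmp_path / "f.bed"
    write_bed([], p)
    assert p.read_text() == ""
    with pytest.raises(FormatError):
        BedRow("c1", 10, 10, "g1", 0, "")
    with pytest.raises(FormatError):
        BedRow("c1", 0, 10, "g1", -1, "")


# ------------------------------------------------------------------ motifs

def test_motif_file_round_trip_and_validation(tmp_path):
    p = tmp_path / "m.txt"
    p.write_text("GANTC\n# a comment\n  gccagg  \n")
    ml = read_motifs(p)
    assert list(ml) == ["GANTC", "GCCAGG"]
    write_motifs(ml, tmp_path / "m2.txt")
    assert list(read_motifs(tmp_path / "m2.txt")) == list(ml)

    (tmp_path / "bad.txt").write_text("GANTC\nGANTC\n")
    with pytest.raises(FormatError, match="duplicate"):
        read_motifs(tmp_path / "bad.txt")
    (tmp_path / "bad2.txt").write_text("GAXTC\n")
    with pytest.raises(FormatError, match="IUPAC"):
        read_motifs(tmp_path / "bad2.txt")


# ------------------------------------------------------------------- Roary

def _roary_csv(tmp_path, rows):
    meta = ",".join(['"m"'] * 13)
    lines = ['"Gene","' + '","'.join(
        ["Non-unique Gene name", "Annotation", "No. isolates",
         "No. sequences", "Avg sequences per isolate", "Genome Fragment",
         "Order within Fragment", "Accessory Fragment",
         "Accessory Order with Fragment", "QC", "Min group size nuc",
         "Max group size nuc", "Avg group size nuc"]) + '","s1","s2"']
    for name, c1, c2 in rows:
        lines.append(f'"{name}","","a, with comma","2","2","1","1","1",'
                     f'"","","","0","0","0","{c1}","{c2}"')
    p = tmp_path / "gene_presence_absence.csv"
    p.write_text("\n".join(lines) + "\n")
    return p


def test_roary_core_vs_dispensable(tmp_path):
    p = _roary_csv(tmp_path, [("geneA", "a_1", "a_2"), ("geneB", "b_1", "")])
    table = read_roary(p)
    assert table.n_strains == 2
    assert table.label("geneA") == "core"
    assert table.label("geneB") == "dispensable"
    assert table.label("missing") == "unknown"
    assert table.label_by_gene_id("b_1") == "dispensable"


def test_roary_counts_recovered(tmp_path):
    rows = [(f"core{i}", f"c{i}_1", f"c{i}_2") for i in range(10)]
    rows += [(f"disp{i}", f"d{i}_1", "") for i in range(5)]
    table = read_roary(_roary_csv(tmp_path, rows))
    labels = [table.label(name) for name, _, _ in rows]
    assert labels.count("core") == 10
    assert labels.count("dispensable") == 5


def test_roary_without_strain_columns_is_error(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text(",".join(f"m{i}" for i in range(14)) + "\n")
    with pytest.raises(FormatError, match="strain"):
        read_roary(p)
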