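# Methods

## Model of the data

The pipeline treats a bacterial methylome as three aligned layers over
one coordinate system: the genome sequence (one or more replicons), a
gene annotation, and a set of single-base modification calls
(m6A/m4C/modified_base) as emitted by SMRT Link. A methylation is
considered *motif-attributable* when its position lies inside an
occurrence of a user-supplied methyltransferase recognition motif **on
the record's own strand** — methylation is a strand-specific mark, and
a record with strand `.` (allowed by the GFF dialect, rare in practice)
is matched permissively against either strand.

Coordinates follow the two formats' conventions: GFF3 1-based
inclusive throughout the pipeline, BED 0-based half-open on output.
Modified-base rows whose interval is wider than 1 bp (occasional 2-bp
contexts) are reduced to the floored midpoint with a warning rather than
rejected, since hard-failing would reject real sequencer files.

## Motif matching

Motifs are IUPAC strings. The scanner is a plain naive window matcher
with early mismatch exit, run once against the pattern (plus-strand
hits) and once against its IUPAC reverse complement (minus-strand hits),
so all coordinates are plus-strand; degeneracy-1 patterns short-circuit
to exact substring search. Worst-case time is O(m·(n−m+1)) per strand,
with the ambiguity codes adding a constant per window.

Two deliberate conventions:

* **Genome `N` matches only motif code `N`.** An unknown base cannot
  evidence methylation; letting `N` satisfy concrete codes would let
  assembly gaps inflate match counts.
* **Palindromic motifs report both strand hits at one locus** (e.g.
  GANTC, the CcrM target, matches every occurrence on both strands).
  Crossing is strand-aware, so collapsing the pair here would destroy
  the CDS/nCDS distinction; a palindromic locus methylated on both
  strands correctly contributes one accordant and one discordant
  record. Consumers who want per-position counts can deduplicate on
  (seqid, start, end).

There is no wraparound across the replicon origin: inputs are treated
as linearized (oriC-oriented) assemblies.

## Feature partition

CDS intervals are the gene bodies; nCDS are the same spans with flipped
strand (a bookkeeping device for antisense methylation, excluded from
coverage arithmetic). The complement of the union of gene bodies is cut
into maximal gaps, each classified from its flanking genes: same
orientation → US owned by the downstream gene in reading order (right
gene for `+`, left for `-`), opposite orientations → tIG (with the
diverging/converging sub-orientation recorded in a `note=` attribute,
since both argue differently about promoter content). Decisions the
between-gene definitions leave open:

* **Terminal gaps.** The gap left of a plus-strand first gene (and
  mirror-image for a minus-strand last gene) is that gene's US;
  otherwise tIG. This keeps the US definition — "the region a gene
  reads out of" — consistent at replicon ends.
* **Upstream range.** By default US is the whole inter-ORF gap. With
  `--upstream-range R` each US is clipped to at most R bp adjacent to
  its owner's reading start and the remainder reclassified tIG.
  Shrinking R is monotone: US bp never grows, tIG bp never shrinks,
  CDS bp is untouched (property-tested).
* **Overlapping genes.** Gene bodies win over intergap; overlapped bp
  is CDS of every overlapping gene, the coverage check downgrades to a
  warning, and a methylation there is credited to each gene while
  summary totals count records, not record-gene pairs.

For non-overlapping annotations the invariant `CDS + US + tIG = replicon
length, zero overlap` is enforced (`partition_report`), which also
guarantees every motif-attributable methylation is categorizable.

## Crossing and statistics

Category assignment per record: inside a gene body, strand-accordant →
CDS else nCDS; in a gap, a same-strand US interval containing the
position → US, else tIG. Consequently flipping every record's strand
swaps CDS and nCDS exactly and keeps records intergenic (a flipped US
record becomes tIG, because US is a strand-accordant promoter notion).
Lookups use bisect-based stabbing indexes; a brute-force triple loop
serves as the oracle in tests.

The statistics log reports, per category, total features, distinct
methylated sites, methylated genes and the most methylated gene with
its product; ties break to the lexicographically smallest geneID purely
for determinism. With a Roary `gene_presence_absence.csv`, each
methylated geneID is labeled core (present in every strain column) or
dispensable; IDs absent from the table are labeled unknown with a
warning. BED rows for US/tIG carry the interval's own coordinates and
the owner geneID (a `left|right` pair for between-gene tIG); zero-count
genes are emitted so the tables double as complete per-gene tables
(`--only-methylated` filters them). Chromosome-level GFF3s are the same
rows regrouped by replicon — header-only files are still written for
empty replicons so downstream globs are deterministic.

## Plots

Every figure writes a numeric TSV twin, and all numeric testing targets
the TSV. Scatter: per-category methylations per gene. Heatmap: motif ×
strain counts, each row scaled by its maximum (all-zero rows stay zero).
Circular: the genome on a polar axis, an outer ring of CDS positions
and four inner rings of per-window counts (default window 10 kb, a
flag; the binning is a presentation choice). Colors: CDS red, nCDS
blue, tIG purple, US yellow.

## Synthetic data

The generator lays out non-overlapping genes (uniform lengths 300–1500
bp, gaps 60–500 bp, strands i.i.d. ±, GC 0.6 — S. meliloti-like) on a
two-replicon 100 kb genome, classifies its own gaps, then plants motif
occurrences per category with the orientation the target category
requires, writing the methylated base at the motif's first
A-compatible position (C for m4C/m5C). The default planting is 40/25/10/5
methylated GANTC hits in CDS/nCDS/tIG/US plus a few unmethylated hits
and stray off-motif calls. Background is iteratively repaired until it
contains no motif occurrence on either strand, so recovery tests are
exact rather than statistical (a `motif_free_background=False` switch
restores realism). Everything is driven by one seed and reproduces
byte-identically.

What the fixture does **not** emulate: kinetics realism (IPD ratios and
modification QVs are decorative), operon structure, overlapping genes,
biased motif spacing, or genome-scale sizes — passing tests demonstrate
the mapping logic is exact under controlled conditions, not that any
biological signal exists. The acceptance script runs on this 100 kb
scale; real multi-Mb genomes run through the same code path, only
longer.

## Numerical and degenerate-input choices

Matches sort by (start, strand) with `+` before `-`; multi-replicon
outputs follow FASTA order. Empty annotation makes the whole replicon a
single tIG. A motif longer than its replicon yields no matches, not an
error. Duplicate motifs, invalid IUPAC codes, duplicate seqids,
out-of-range coordinates and unresolvable seqids are hard errors at
load/validate time, before any processing.
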