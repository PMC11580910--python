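# Methods

## Data model

Annotation and expression tables are plain pandas DataFrames with documented
column contracts rather than wrapper classes, so users can slice, join and
inspect them with ordinary pandas idioms.  Annotation rows carry 1-based
inclusive genomic coordinates (the GTF convention) end to end; the only
place a different coordinate system appears is gap shortening, which writes
unitless display coordinates into `start`/`end` and preserves the genomic
originals in `genomic_start`/`genomic_end` companion columns.  Keeping both
avoids a lossy convention change at the I/O boundary and lets hover text
report genomic positions after rescaling.

## GTF reading

Only `exon` and `CDS` rows are loaded; everything else (gene bodies, UTRs,
codons) is dropped, since the figure is assembled from exons, per-exon CDS
segments, and introns derived from the exons.  Validation is deliberately
strict where guessing would corrupt output silently: a data line must have
exactly nine tab-separated fields (reported with its line number), retained
rows must carry `gene_id` and `transcript_id`, and strand must be `+` or `-`
— `.`/`?` strands are rejected rather than defaulted because strand drives
exon numbering.  A missing `transcript_biotype` becomes an empty string
(not every GTF dialect carries it); missing `gene_name`/`transcript_name`
are filled from the identifiers.  Gzip input is detected by magic bytes, not
extension, so renamed files still load.  `exon_number` attributes present in
the file are trusted on load but left unset (nullable integer) when absent;
`calculate_exon_number` recomputes and overwrites them on demand, which is
what supports annotation sources that ship no exon numbers.

## Expression loading and normalization

Matrices in `.tsv/.txt/.csv/.xlsx/.parquet` are accepted, wide or long.
Orientation is auto-detected: if the transcript-identifier column exists and
every other non-identifier column is numeric, the matrix is wide and is
melted; otherwise it must already carry `sample_id` and `counts` columns.
The metadata merge is strict on the matrix side (a matrix sample without a
metadata row raises, listing the samples) and permissive on the metadata
side (extra rows dropped with a logged count) — silently losing samples from
plots is the worse failure.

CPM uses the library size of the full loaded matrix, computed before any
gene filtering; filtering first would inflate values because CPM is a
library-level normalization.  Relative transcript abundance is expressed as
a percentage in [0, 100], matching the axis convention of isoform-usage
plots.  Zero library sizes and zero gene totals produce 0 (with a warning
for the former), never NaN, so downstream glyphs always render.

## Gene filtering and ranking

The target gene is matched against `gene_id` first, then `gene_name`; an
unknown gene raises with the nearest matches (difflib over both
namespaces).  When expression is supplied it is synchronized to the
transcripts of the filtered annotation.  Ranking ("top expressed") sums raw
counts by default — counts are the one measure always present — with ties
broken lexicographically by transcript id so output order is deterministic
across runs.  Because "top expressed" is undefined without an expression
table, `order_by_expression` and `keep_top_n` require one and raise a
configuration error otherwise.  Filtering is idempotent.

## Introns and exon numbers

Introns use the visual-abutment convention: intron start = upstream exon
end, intron end = downstream exon start, endpoints shared with the flanking
exons so rendered shapes touch without 1-bp gaps.  These coordinates feed
rendering, not sequence extraction, so the off-by-one relative to a
sequence-level intron definition is intentional.  Genomically abutting exons
(no base strictly between them, i.e. end − start ≤ 1 under this convention)
yield no intron: such a sliver is unrenderable and biologically spurious.

Exon numbering is 1..n in transcription order (ascending start on `+`,
descending on `-`).  CDS rows are required to be per-exon segments — a CDS
overlapping zero or two exons of its transcript is a validation error — and
inherit the containing exon's number.  Introns take the number of their
5′-flanking exon in transcription order, which makes the intron numbers of
a transcript exactly {1..n−1} symmetrically on both strands.

## Gap shortening

The coordinate map is global, built from the union of exon intervals across
*all* plotted transcripts: a region is compressible only if it is intronic
or intergenic in every transcript.  This is what guarantees the two
invariants the figure depends on — exon/CDS widths are conserved exactly
(they lie inside union blocks, where the map is a pure shift) and exons
identical in genomic coordinates land on identical display coordinates in
every transcript.  Compressing per transcript instead would misalign shared
exons.  Transcript start gaps need no special case: the same global map
compresses the region upstream of a late-starting transcript's first exon.

Numerical choices: width is `end − start` in both spaces; each gap of width
w is assigned display width min(w, t) with t = 100 display units by default
(long introns stay visible but subordinate); a gap exactly equal to the
target keeps its width (either choice gives the same width; retaining makes
"compressed" mean strictly narrower).  Within a compressed gap the first t
units map identically and the remainder collapses onto the gap's right edge
— no proportional scaling inside gaps — which makes the piecewise map agree
*exactly* with a brute-force oracle that remaps every integer coordinate
independently; that equivalence, exercised over hundreds of seeded genes, is
the core correctness test.  The global minimum exon start maps to 0.

## Figure composition and export

A trace set is a renderer-independent description: exon rectangles at 0.30
of the row height, CDS rectangles at 0.50 (the classic thin-UTR/thick-CDS
gene-model idiom), introns as center lines, plus one distributional glyph
per (transcript, sample group, measure).  The default glyph is a box plot —
the least assumption-laden distributional summary; violin and bar styles
are selectable.  Colors come from a fixed colorblind-aware categorical
palette keyed by transcript, overridable per feature type or metadata group.
Optional strand chevrons on introns are off by default.

Panels are arranged horizontally: structure leftmost, one panel per
expression measure, all sharing a single inverted row axis (first transcript
on top) so rows line up across panels by construction.  Transcript row order
is the order produced by gene filtering, which ties the structure panel to
the expression ranking.

HTML export is a self-contained document: the figure as inline SVG with
hover tooltips via SVG `<title>` elements and a small embedded script for
wheel zoom and drag pan — no network fetch is needed to display it.  The
SVG serialization contains no timestamps or random identifiers and formats
coordinates at fixed precision, so identical inputs produce byte-identical
payloads (tested).  SVG export writes the same document standalone; PNG and
PDF are rendered from the same FigureSpec with matplotlib's Agg backend.

## Synthetic data generator

The generator emulates a small two-condition isoform-expression experiment:
a multi-transcript gene locus whose isoforms share a promoter region
(transcript starts within 400 bp), exon counts 2–8, exon widths 50–300 bp,
intron widths 100–2000 bp, most transcripts carrying per-exon CDS segments
(probability 0.7); counts are negative-binomial (dispersion 5) around
per-transcript lognormal base means (median 200), with a 3× multiplicative
group effect on a seeded half of the transcripts in every group after the
first, and samples assigned to groups evenly.  Defaults were chosen once as
a plausible compact human protein-coding gene; tests narrow the ranges where
an oracle needs small spans (e.g. per-base coverage, ≤ 10 kb genes for the
rescaling oracle).  All randomness flows from a single integer seed through
a local `numpy.random.Generator`; equal seeds give byte-identical files.
Written GTFs interleave distractor `gene`/`five_prime_utr` lines and omit
`exon_number` on a seeded half of transcripts, exercising the exon/CDS-only
loading contract and the renumbering path.

What the generator does not emulate: splice-site sequence content,
read-level noise, library composition effects, overlapping genes on one
locus, or trans-chromosomal structures.  Passing tests therefore establish
the interval arithmetic, normalization algebra, rendering contracts and
determinism of the pipeline — not robustness to every annotation pathology
in real reference files (e.g. transcripts split across assemblies patches).

## Problem sizes

The default test suite and the acceptance script use compact problem sizes
chosen to exercise every code path with exact oracles: 200 genes for the
rescaling oracle (spans ≤ 10 kb so per-integer remapping is cheap), 100
matrices for normalization conservation, 200 transcripts per strand for
numbering, 50 end-to-end pipeline runs with 10 repeated-run determinism
checks, and a 20-gene batch for the one-figure-per-gene count.  A full
chromosome-scale batch run uses the same code path via
`count_gene_figures`.

## Known limitations

- GFF3 is not parsed; only the GTF `key "value";` attribute dialect.
- Gap compression is global and uniform; per-intron modes and logarithmic
  axes are out of scope.
- Between-sample normalizations beyond CPM (TMM, DESeq size factors) and
  any differential testing are out of scope.
- The interactive HTML offers hover/zoom/pan but not panel relayout or
  client-side data filtering.
- Multi-gene loci cannot share one structure panel; batch rendering emits
  one figure per gene.
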