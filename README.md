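# isoviz

Interactive, programmable visualization of RNA isoform structure and
expression for bulk and single-cell transcriptomics.

Alternative splicing lets one gene produce many RNA isoforms, and long-read
sequencing now quantifies them directly — but interpreting the results still
means looking at them: which exons does each isoform keep, where is the
coding sequence, and how does expression differ between conditions?  isoviz
renders a gene's isoforms as aligned gene models (thin exon boxes, thick CDS
boxes, intron lines) side by side with per-isoform expression panels, from
two inputs a transcriptomics workflow already has: an ENSEMBL-dialect GTF
annotation and an expression count matrix.

## What it computes

- **Intron derivation.** For each transcript with exons at genomic intervals
  $(s_1,e_1) < \dots < (s_n,e_n)$ (1-based inclusive), the $n-1$ introns are
  the intervals $(e_i, s_{i+1})$ between consecutive exons (endpoints shared
  with the flanking exons so drawn shapes abut).
- **Strand-aware exon numbering.** Exons are numbered $1..n$ in
  transcription (5′→3′) order: ascending genomic start on the `+` strand,
  descending on the `-` strand.  A CDS segment inherits the number of the
  exon containing it; an intron inherits the number of its 5′-flanking exon,
  so introns carry exactly $\{1..n-1\}$ on either strand.
- **Intron gap shortening.** One monotone map is built from the union of all
  plotted exons: union blocks keep their width, each complement gap of width
  $w$ is compressed to $\min(w, t)$ for a target width $t$ (default 100
  display units), and rescaled starts accumulate from 0.  Exon and CDS
  widths are conserved exactly and identical genomic exons stay aligned
  across transcripts; transcript start gaps are compressed by the same map.
- **Normalization.** CPM, $\mathrm{cpm}_{st} = 10^6\, c_{st} / \sum_{t'}
  c_{st'}$ per sample $s$ (library size taken over the full matrix, before
  gene filtering), and relative transcript abundance, a transcript's
  percentage of its gene's counts in a sample: $100\, c_{st} / \sum_{t' \in
  g} c_{st'}$ (0 where the gene total is 0).
- **Figure composition.** A declarative trace set (rectangles, lines,
  box/violin/bar glyphs) arranged into a structure panel plus one panel per
  expression measure, all sharing an inverted transcript axis.  Export:
  self-contained interactive HTML (hover tooltips report original genomic
  coordinates even after rescaling; wheel zoom, drag pan), or static
  SVG/PNG/PDF.

## Worked example

Generate a synthetic gene with matched counts and plot it:

```sh
isoviz make-fixtures --out-dir demo --seed 11
isoviz --verbose plot-gene \
    --gtf demo/annotation.gtf --counts demo/counts.tsv \
    --metadata demo/metadata.tsv --gene GENE1 \
    --gene-id-column gene_id --group-by group --top-n 3 \
    --out demo/GENE1.html
```

which logs the pipeline stages and confirms the output:

```
INFO isoviz.pipeline: annotation: 45 exon/CDS rows
INFO isoviz.pipeline: expression: 40 long rows
INFO isoviz.pipeline: gene GENE1: 22 annotation rows, 3 transcripts
INFO isoviz.pipeline: gene GENE1: 34 rows after intron derivation and rescaling
wrote demo/GENE1.html
```

The 45 exon/CDS rows are the five generated transcripts; `--top-n 3` keeps
the three with the highest total counts (22 rows), intron derivation and
rescaling add the 12 intron rows (34 total), and the figure shows those
three isoforms' structures next to per-group count boxplots.  The same
pipeline is available as library calls
(`read_annotation → gene_filtering → to_intron → calculate_exon_number →
shorten_gaps → make_traces → make_plot → export`), and
`isoviz rescale` exports the gap-shortened coordinates as a TSV for
inspection.

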