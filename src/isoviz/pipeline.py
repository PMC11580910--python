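"""End-to-end composition: annotation + counts → exported figure.

This is the library-level equivalent of the ``isoviz plot-gene`` command:
read → filter to one gene → derive introns → number exons → shorten gaps →
build traces → compose panels → export.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import annotation as ann_io
from . import expression as expr_io
from .figure import FigureSpec, export, make_plot
from .rescale import DEFAULT_TARGET_GAP_WIDTH, shorten_gaps
from .structure import calculate_exon_number, gene_filtering, to_intron
from .traces import make_traces

logger = logging.getLogger(__name__)


def build_gene_figure(
    annotation: pd.DataFrame,
    expression: pd.DataFrame | None,
    gene: str,
    *,
    top_n: int | None = None,
    order_by_expression: bool = False,
    measure: str = "counts",
    target_gap_width: int = DEFAULT_TARGET_GAP_WIDTH,
    style: dict | None = None,
    layout: dict | None = None,
) -> FigureSpec:
    """Run the full structural pipeline for one gene and compose the figure."""
    ann, expr = gene_filtering(
        annotation,
        expression,
        gene=gene,
        order_by_expression=order_by_expression and expression is not None,
        keep_top_n=top_n,
        measure=measure,
    )
    logger.info("gene %s: %d annotation rows, %d transcripts", gene, len(ann),
                ann["transcript_id"].nunique())
    ann = to_intron(ann)
    ann = calculate_exon_number(ann)
    ann = shorten_gaps(ann, target_gap_width)
    logger.info("gene %s: %d rows after intron derivation and rescaling", gene, len(ann))

    style = dict(style or {})
    if expr is not None and "measures" not in style:
        style["measures"] = [measure]
    traces = make_traces(ann, expr, style=style)
    return make_plot(traces, layout=layout)


def plot_gene(
    gtf_path: str | Path,
    gene: str,
    out_path: str | Path,
    *,
    counts_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
    sample_id_column: str = "sample_id",
    transcript_id_column: str = "transcript_id",
    gene_id_column: str | None = None,
    group_by: str | None = None,
    top_n: int | None = None,
    measure: str = "counts",
    target_gap_width: int = DEFAULT_TARGET_GAP_WIDTH,
    format: str = "html",
    style: dict | None = None,
    layout: dict | None = None,
) -> FigureSpec:
    """File-to-file convenience wrapper: read inputs, build, export."""
    table = ann_io.read_annotation(gtf_path)
    logger.info("annotation: %d exon/CDS rows", len(table))
    expr = None
    if counts_path is not None:
        expr = expr_io.read_expression(
            counts_path,
            metadata_path,
            sample_id_column=sample_id_column,
            transcript_id_column=transcript_id_column,
            gene_id_column=gene_id_column,
            compute_cpm=measure == "cpm",
            compute_relative_abundance=measure == "relative_abundance",
        )
        logger.info("expression: %d long rows", len(expr))
    style = dict(style or {})
    if group_by is not None:
        style["group_by"] = group_by
    fig = build_gene_figure(
        table, expr, gene,
        top_n=top_n,
        order_by_expression=expr is not None,
        measure=measure,
        target_gap_width=target_gap_width,
        style=style,
        layout=layout,
    )
    export(fig, out_path, format)
    return fig


def count_gene_figures(
    annotation: pd.DataFrame,
    out_dir: str | Path | None = None,
    *,
    seqnames: list[str] | None = None,
    format: str = "html",
    target_gap_width: int = DEFAULT_TARGET_GAP_WIDTH,
) -> int:
    """Render one structure figure per gene; return the number produced.

    Optionally restricted to the given seqnames (e.g. specific chromosomes).
    When *out_dir* is None the figures are composed but not written, which
    still exercises the full per-gene pipeline.
    """
    if seqnames is not None:
        annotation = annotation[annotation["seqname"].isin(seqnames)]
    n = 0
    for gene_id, grp in annotation.groupby("gene_id", sort=True):
        ann = calculate_exon_number(to_intron(grp.reset_index(drop=True)))
        ann = shorten_gaps(ann, target_gap_width)
        fig = make_plot(make_traces(ann))
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            export(fig, out / f"{gene_id}.{format}", format)
        n += 1
    return n
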