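"""Declarative trace descriptors for one gene's structure/expression figure.

A :class:`TraceSet` is a renderer-independent description of everything the
figure will draw: exon and CDS rectangles, intron lines, and per-(transcript,
group) expression glyphs.  Renderers (see :mod:`isoviz.figure`) turn it into
SVG/HTML or static images without re-touching the data tables.

Drawing idiom: exons are rectangles at 0.30 of the row height, CDS segments
are thicker rectangles at 0.50 (coding regions visually dominant — the
classic thin-UTR/thick-CDS gene model), introns are lines at row center.
Hover text always reports ORIGINAL genomic coordinates, taken from the
``genomic_start``/``genomic_end`` companion columns after gap shortening.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ConfigurationError, SynchronizationError, ValidationError

#: Deterministic categorical palette (colorblind-aware, hex).
DEFAULT_PALETTE = [
    "#0173b2", "#de8f05", "#029e73", "#d55e00", "#cc78bc",
    "#ca9161", "#fbafe4", "#949494", "#ece133", "#56b4e9",
]

EXON_HEIGHT = 0.30
CDS_HEIGHT = 0.50


@dataclass(frozen=True)
class Shape:
    """One structure-panel drawing instruction."""

    kind: str  # "rect" | "line"
    x_start: float
    x_end: float
    row: int
    height: float  # fraction of the row; 0 for lines
    fill_color: str
    line_width: float
    hover_text: str


@dataclass(frozen=True)
class ExpressionGlyph:
    """One distributional glyph: a (transcript row, sample group) cell."""

    row: int
    group_label: str
    values: tuple[float, ...]
    style: str  # "box" | "violin" | "bar"
    measure: str
    fill_color: str


@dataclass
class TraceSet:
    """Ordered shape/glyph descriptors plus the shared row labels."""

    structure_shapes: list[Shape] = field(default_factory=list)
    expression_glyphs: list[ExpressionGlyph] = field(default_factory=list)
    row_labels: list[str] = field(default_factory=list)

    @property
    def measures(self) -> list[str]:
        seen: list[str] = []
        for g in self.expression_glyphs:
            if g.measure not in seen:
                seen.append(g.measure)
        return seen

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.expression_glyphs:
            if g.group_label not in seen:
                seen.append(g.group_label)
        return seen


#: Recognized style options and their defaults (flat mapping, CLI-loadable).
DEFAULT_STYLE: dict = {
    "exon_height": EXON_HEIGHT,
    "cds_height": CDS_HEIGHT,
    "intron_line_width": 1.5,
    "exon_line_width": 0.5,
    "color_by": "transcript",  # "transcript" | "feature_type" | "group"
    "palette": DEFAULT_PALETTE,
    "colors": None,  # explicit {key: color} override
    "group_by": None,  # metadata column for expression grouping
    "measures": None,  # expression measures to build glyphs for
    "glyph_style": "box",  # "box" | "violin" | "bar"
    "strand_arrows": False,
}

_KNOWN_MEASURES = ("counts", "cpm", "relative_abundance")


def _resolve_style(style: dict | None) -> dict:
    resolved = dict(DEFAULT_STYLE)
    if style:
        unknown = set(style) - set(DEFAULT_STYLE)
        if unknown:
            raise ConfigurationError(f"unknown style options: {sorted(unknown)}")
        resolved.update(style)
    return resolved


def _color_for(key: str, index: int, style: dict) -> str:
    if style["colors"] and key in style["colors"]:
        return style["colors"][key]
    palette = style["palette"]
    return palette[index % len(palette)]


def _hover(row: pd.Series) -> str:
    gstart = row.get("genomic_start", row["start"])
    gend = row.get("genomic_end", row["end"])
    num = row.get("exon_number")
    num_part = "" if pd.isna(num) else f" {int(num)}"
    return (
        f"{row['transcript_name']} | {row['feature_type']}{num_part} | "
        f"{row['seqname']}:{int(gstart)}-{int(gend)} ({row['strand']})"
    )


def make_traces(
    annotation: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    style: dict | None = None,
) -> TraceSet:
    """Build the trace set for one gene.

    One row per transcript, in order of first appearance in *annotation*
    (i.e. the order produced by gene filtering, expression-ranked when that
    was enabled).  Expression glyphs are grouped by the ``group_by`` metadata
    column (a single group when unset), one glyph per (transcript, group,
    measure).

    Raises
    ------
    ValidationError
        Annotation containing more than one gene.
    SynchronizationError
        Expression transcripts absent from the annotation.
    ConfigurationError
        Unknown style options or an unavailable grouping column/measure.
    """
    style = _resolve_style(style)

    genes = annotation["gene_id"].unique()
    if len(genes) != 1:
        raise ValidationError(f"expected exactly one gene, got {len(genes)}: {sorted(genes)}")

    transcripts = list(dict.fromkeys(annotation["transcript_id"]))
    row_of = {t: i for i, t in enumerate(transcripts)}
    names = annotation.drop_duplicates("transcript_id").set_index("transcript_id")[
        "transcript_name"
    ]
    row_labels = [str(names[t]) for t in transcripts]

    if expression is not None:
        stray = set(expression["transcript_id"]) - set(transcripts)
        if stray:
            raise SynchronizationError(
                f"expression transcripts absent from annotation: {sorted(stray)}"
            )

    shapes: list[Shape] = []
    for _, r in annotation.iterrows():
        row = row_of[r["transcript_id"]]
        if style["color_by"] == "feature_type":
            color = _color_for(r["feature_type"], ("exon", "CDS", "intron").index(r["feature_type"]), style)
        else:
            color = _color_for(r["transcript_id"], row, style)
        if r["feature_type"] == "intron":
            shapes.append(
                Shape("line", float(r["start"]), float(r["end"]), row, 0.0,
                      color, style["intron_line_width"], _hover(r))
            )
            if style["strand_arrows"]:
                shapes.extend(_arrow_shapes(r, row, color, style))
        else:
            height = style["cds_height"] if r["feature_type"] == "CDS" else style["exon_height"]
            shapes.append(
                Shape("rect", float(r["start"]), float(r["end"]), row, height,
                      color, style["exon_line_width"], _hover(r))
            )

    glyphs: list[ExpressionGlyph] = []
    if expression is not None:
        glyphs = _make_glyphs(expression, row_of, style)

    return TraceSet(structure_shapes=shapes, expression_glyphs=glyphs, row_labels=row_labels)


def _arrow_shapes(r: pd.Series, row: int, color: str, style: dict) -> list[Shape]:
    """A chevron at the intron midpoint indicating transcription direction."""
    mid = (float(r["start"]) + float(r["end"])) / 2.0
    span = max((float(r["end"]) - float(r["start"])) * 0.04, 1.0)
    tip = mid + span if r["strand"] == "+" else mid - span
    hover = _hover(r)
    lw = style["intron_line_width"]
    return [
        Shape("line", mid - (tip - mid), tip, row, 0.12, color, lw, hover),
        Shape("line", mid - (tip - mid), tip, row, -0.12, color, lw, hover),
    ]


def _make_glyphs(
    expression: pd.DataFrame, row_of: dict[str, int], style: dict
) -> list[ExpressionGlyph]:
    group_by = style["group_by"]
    if group_by is not None and group_by not in expression.columns:
        raise ConfigurationError(f"grouping column {group_by!r} not in expression table")

    measures = style["measures"]
    if measures is None:
        measures = [m for m in _KNOWN_MEASURES if m in expression.columns]
    missing = [m for m in measures if m not in expression.columns]
    if missing:
        raise ConfigurationError(f"expression table lacks measure column(s) {missing}")

    expr = expression.copy()
    expr["_group"] = expr[group_by].astype(str) if group_by is not None else "all"
    groups = sorted(expr["_group"].unique())

    glyphs: list[ExpressionGlyph] = []
    for measure in measures:
        for tx, row in row_of.items():
            sub = expr[expr["transcript_id"] == tx]
            for gi, group in enumerate(groups):
                values = sub.loc[sub["_group"] == group, measure]
                if values.empty:
                    continue
                color = _color_for(group, gi, style) if group_by is not None else _color_for(tx, row, style)
                glyphs.append(
                    ExpressionGlyph(
                        row=row,
                        group_label=group,
                        values=tuple(float(v) for v in values),
                        style=style["glyph_style"],
                        measure=measure,
                        fill_color=color,
                    )
                )
    return glyphs


def shape_counts(traces: TraceSet) -> dict[int, dict[str, int]]:
    """Per-row counts of rects and lines (invariant: rects = exons + CDS)."""
    counts: dict[int, dict[str, int]] = {}
    for s in traces.structure_shapes:
        counts.setdefault(s.row, {"rect": 0, "line": 0})[s.kind] += 1
    return counts
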