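"""Compose trace sets into multi-panel figures and export them.

A :class:`FigureSpec` arranges one structure panel plus zero or more
expression panels horizontally, all sharing a single inverted row axis (first
transcript on top).  Export targets:

``html``
    A self-contained interactive document: the figure rendered as inline SVG
    with per-shape hover tooltips (SVG ``<title>``) and wheel-zoom/drag-pan
    driven by a small embedded script.  No network access is needed to view
    it, and the serialized shape payload is deterministic — no timestamps or
    random identifiers — so identical inputs give identical payloads.
``svg``
    The same deterministic SVG as a standalone file.
``png`` / ``pdf``
    Static raster/vector renders of the same FigureSpec via matplotlib.
"""

from __future__ import annotations

import html as _html
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .traces import ExpressionGlyph, Shape, TraceSet

_MEASURE_LABELS = {
    "counts": "Counts",
    "cpm": "CPM",
    "relative_abundance": "Relative abundance (%)",
}

#: Recognized layout options and their defaults.
DEFAULT_LAYOUT: dict = {
    "width": 960,
    "row_height": 36,
    "structure_fraction": 0.5,  # width fraction of the structure panel
    "font_family": "Helvetica, Arial, sans-serif",
    "font_size": 11,
    "background": "#ffffff",
    "title": None,
    "measures": None,  # expression panels to include; None = all present
    "label_width": 150,  # left margin for transcript labels
}


@dataclass(frozen=True)
class Panel:
    """One subplot: the structure panel or one expression measure."""

    kind: str  # "structure" | "expression"
    title: str
    measure: str | None = None
    shapes: tuple[Shape, ...] = ()
    glyphs: tuple[ExpressionGlyph, ...] = ()


@dataclass
class FigureSpec:
    """Panel layout + axes + interactivity metadata for one figure."""

    panels: list[Panel]
    row_labels: list[str]
    shared_row_axis: bool = True
    layout: dict = field(default_factory=lambda: dict(DEFAULT_LAYOUT))
    interactivity: dict = field(default_factory=lambda: {"hover": True, "zoom": True})


def make_plot(traces: TraceSet, layout: dict | None = None) -> FigureSpec:
    """Arrange a trace set into a figure: structure panel leftmost, one
    horizontally arranged panel per requested expression measure, all sharing
    the inverted row axis.

    Raises
    ------
    ConfigurationError
        Empty traces, an unknown layout option, or an expression panel
        requested for a measure with no glyphs.
    """
    if not traces.structure_shapes and not traces.expression_glyphs:
        raise ConfigurationError("cannot plot an empty trace set")
    resolved = dict(DEFAULT_LAYOUT)
    if layout:
        unknown = set(layout) - set(DEFAULT_LAYOUT)
        if unknown:
            raise ConfigurationError(f"unknown layout options: {sorted(unknown)}")
        resolved.update(layout)

    measures = resolved["measures"]
    if measures is None:
        measures = traces.measures
    panels = [Panel("structure", "Transcript structure", shapes=tuple(traces.structure_shapes))]
    for m in measures:
        glyphs = tuple(g for g in traces.expression_glyphs if g.measure == m)
        if not glyphs:
            raise ConfigurationError(f"expression panel requested for {m!r} but no glyphs exist")
        panels.append(Panel("expression", _MEASURE_LABELS.get(m, m), measure=m, glyphs=glyphs))

    return FigureSpec(panels=panels, row_labels=list(traces.row_labels), layout=resolved)


def export(figure: FigureSpec, path, format: str) -> None:
    """Write the figure to *path* in the given format.

    Raises
    ------
    ConfigurationError
        Unsupported format.
    OSError
        Unwritable path.
    """
    if format == "html":
        svg = render_svg(figure)
        _write_text(path, _wrap_html(figure, svg))
    elif format == "svg":
        _write_text(path, render_svg(figure))
    elif format in ("png", "pdf"):
        _render_matplotlib(figure, path, format)
    else:
        raise ConfigurationError(
            f"unsupported export format {format!r}; expected html, png, svg or pdf"
        )


def _write_text(path, text: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# geometry shared by both renderers
# ---------------------------------------------------------------------------

def _nice_ticks(lo: float, hi: float, n: int = 5) -> list[float]:
    """About *n* round tick positions covering [lo, hi]."""
    if hi <= lo:
        hi = lo + 1.0
    raw = (hi - lo) / n
    mag = 10 ** math.floor(math.log10(raw))
    for m in (1, 2, 2.5, 5, 10):
        step = m * mag
        if step >= raw:
            break
    first = math.ceil(lo / step) * step
    ticks = []
    t = first
    while t <= hi + 1e-9:
        ticks.append(round(t, 10))
        t += step
    return ticks


def _panel_xrange(panel: Panel) -> tuple[float, float]:
    if panel.kind == "structure":
        xs = [s.x_start for s in panel.shapes] + [s.x_end for s in panel.shapes]
        lo, hi = min(xs), max(xs)
        pad = (hi - lo) * 0.02 or 1.0
        return lo - pad, hi + pad
    values = [v for g in panel.glyphs for v in g.values]
    hi = max(values) if values else 1.0
    return 0.0, hi * 1.08 if hi > 0 else 1.0


@dataclass(frozen=True)
class _BoxStats:
    lo_whisker: float
    q1: float
    median: float
    q3: float
    hi_whisker: float


def _box_stats(values: tuple[float, ...]) -> _BoxStats:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo = float(arr[arr >= q1 - 1.5 * iqr].min())
    hi = float(arr[arr <= q3 + 1.5 * iqr].max())
    return _BoxStats(lo, float(q1), float(med), float(q3), hi)


def _violin_outline(values: tuple[float, ...], bins: int = 8) -> list[tuple[float, float]]:
    """Histogram-based (value, half-width fraction) outline for a violin."""
    arr = np.asarray(values, dtype=float)
    if arr.min() == arr.max():
        return [(float(arr.min()), 1.0), (float(arr.max()), 1.0)]
    hist, edges = np.histogram(arr, bins=bins, density=True)
    peak = hist.max() or 1.0
    centers = (edges[:-1] + edges[1:]) / 2
    return [(float(c), float(h / peak)) for c, h in zip(centers, hist)]


# ---------------------------------------------------------------------------
# SVG renderer (deterministic; hover via <title>)
# ---------------------------------------------------------------------------

def _f(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def render_svg(figure: FigureSpec) -> str:
    """Render the figure to a deterministic standalone SVG string."""
    lay = figure.layout
    n_rows = max(len(figure.row_labels), 1)
    row_h = lay["row_height"]
    label_w = lay["label_width"]
    top = 34 if lay["title"] or len(figure.panels) else 34
    bottom = 40
    width = lay["width"]
    height = top + n_rows * row_h + bottom

    plot_w = width - label_w - 20
    n_panels = len(figure.panels)
    gap = 18
    if n_panels == 1:
        panel_widths = [plot_w]
    else:
        sw = plot_w * lay["structure_fraction"]
        rest = (plot_w - sw - gap * (n_panels - 1)) / (n_panels - 1)
        panel_widths = [sw] + [rest] * (n_panels - 1)

    parts: list[str] = []
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{_f(height)}" '
        f'viewBox="0 0 {width} {_f(height)}" font-family="{lay["font_family"]}" '
        f'font-size="{lay["font_size"]}">'
    )
    parts.append(f'<rect width="{width}" height="{_f(height)}" fill="{lay["background"]}"/>')
    if lay["title"]:
        parts.append(
            f'<text x="{_f(width / 2)}" y="16" text-anchor="middle" '
            f'font-weight="bold">{_esc(lay["title"])}</text>'
        )

    def row_center(i: int) -> float:
        return top + (i + 0.5) * row_h  # row 0 on top: inverted axis

    # Shared row labels, left of the first panel.
    for i, label in enumerate(figure.row_labels):
        parts.append(
            f'<text x="{label_w - 8}" y="{_f(row_center(i) + 3.5)}" '
            f'text-anchor="end">{_esc(label)}</text>'
        )

    x0 = float(label_w)
    for panel, pw in zip(figure.panels, panel_widths):
        parts.append(_render_panel_svg(panel, x0, pw, top, row_h, n_rows, lay))
        x0 += pw + gap
    parts.append("</svg>")
    return "\n".join(parts)


def _esc(text: str) -> str:
    return _html.escape(str(text), quote=True)


def _render_panel_svg(
    panel: Panel, x0: float, pw: float, top: float, row_h: float, n_rows: int, lay: dict
) -> str:
    lo, hi = _panel_xrange(panel)
    span = hi - lo

    def sx(x: float) -> float:
        return x0 + (x - lo) / span * pw

    plot_h = n_rows * row_h
    out = [f'<g class="panel panel-{panel.kind}">']
    out.append(
        f'<text x="{_f(x0 + pw / 2)}" y="{_f(top - 8)}" text-anchor="middle" '
        f'font-weight="bold">{_esc(panel.title)}</text>'
    )
    # frame + x axis
    out.append(
        f'<rect x="{_f(x0)}" y="{_f(top)}" width="{_f(pw)}" height="{_f(plot_h)}" '
        f'fill="none" stroke="#cccccc" stroke-width="1"/>'
    )
    for t in _nice_ticks(lo, hi):
        if not (lo <= t <= hi):
            continue
        tx = sx(t)
        out.append(
            f'<line x1="{_f(tx)}" y1="{_f(top + plot_h)}" x2="{_f(tx)}" '
            f'y2="{_f(top + plot_h + 4)}" stroke="#888888" stroke-width="1"/>'
        )
        label = f"{t:g}" if abs(t) < 1e6 else f"{t:.2e}"
        out.append(
            f'<text x="{_f(tx)}" y="{_f(top + plot_h + 15)}" '
            f'text-anchor="middle">{_esc(label)}</text>'
        )

    def row_center(i: int) -> float:
        return top + (i + 0.5) * row_h

    if panel.kind == "structure":
        for s in panel.shapes:
            cy = row_center(s.row)
            title = f"<title>{_esc(s.hover_text)}</title>"
            if s.kind == "rect":
                h = s.height * row_h
                out.append(
                    f'<rect x="{_f(sx(s.x_start))}" y="{_f(cy - h / 2)}" '
                    f'width="{_f(max(sx(s.x_end) - sx(s.x_start), 0.5))}" height="{_f(h)}" '
                    f'fill="{s.fill_color}" stroke="#333333" '
                    f'stroke-width="{_f(s.line_width)}">{title}</rect>'
                )
            else:
                # height is the vertical rise fraction; introns are flat (0)
                y1 = cy - s.height * row_h
                out.append(
                    f'<line x1="{_f(sx(s.x_start))}" y1="{_f(y1)}" '
                    f'x2="{_f(sx(s.x_end))}" y2="{_f(cy)}" stroke="{s.fill_color}" '
                    f'stroke-width="{_f(s.line_width)}">{title}</line>'
                )
    else:
        groups: list[str] = []
        for g in panel.glyphs:
            if g.group_label not in groups:
                groups.append(g.group_label)
        n_groups = max(len(groups), 1)
        slot = row_h * 0.72 / n_groups
        for g in panel.glyphs:
            gi = groups.index(g.group_label)
            cy = row_center(g.row) - row_h * 0.36 + (gi + 0.5) * slot
            out.append(_render_glyph_svg(g, sx, cy, slot * 0.8))
        out.append("</g>")
        return "\n".join(out)
    out.append("</g>")
    return "\n".join(out)


def _render_glyph_svg(g: ExpressionGlyph, sx, cy: float, gh: float) -> str:
    n = len(g.values)
    mean = sum(g.values) / n
    hover = (
        f"{g.group_label} | {g.measure} | n={n} | mean={mean:.3g}"
    )
    title = f"<title>{_esc(hover)}</title>"
    parts = [f'<g class="glyph">']
    if g.style == "box":
        st = _box_stats(g.values)
        parts.append(
            f'<line x1="{_f(sx(st.lo_whisker))}" y1="{_f(cy)}" '
            f'x2="{_f(sx(st.hi_whisker))}" y2="{_f(cy)}" stroke="#333333" stroke-width="1"/>'
        )
        parts.append(
            f'<rect x="{_f(sx(st.q1))}" y="{_f(cy - gh / 2)}" '
            f'width="{_f(max(sx(st.q3) - sx(st.q1), 0.5))}" height="{_f(gh)}" '
            f'fill="{g.fill_color}" stroke="#333333" stroke-width="1">{title}</rect>'
        )
        parts.append(
            f'<line x1="{_f(sx(st.median))}" y1="{_f(cy - gh / 2)}" '
            f'x2="{_f(sx(st.median))}" y2="{_f(cy + gh / 2)}" '
            f'stroke="#333333" stroke-width="1.5"/>'
        )
    elif g.style == "violin":
        outline = _violin_outline(g.values)
        upper = [(sx(v), cy - w * gh / 2) for v, w in outline]
        lower = [(sx(v), cy + w * gh / 2) for v, w in reversed(outline)]
        pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in upper + lower)
        parts.append(
            f'<polygon points="{pts}" fill="{g.fill_color}" fill-opacity="0.7" '
            f'stroke="#333333" stroke-width="1">{title}</polygon>'
        )
    else:  # bar: mean with SD whisker
        sd = float(np.std(np.asarray(g.values, dtype=float)))
        parts.append(
            f'<rect x="{_f(sx(0.0))}" y="{_f(cy - gh / 2)}" '
            f'width="{_f(max(sx(mean) - sx(0.0), 0.5))}" height="{_f(gh)}" '
            f'fill="{g.fill_color}" stroke="#333333" stroke-width="1">{title}</rect>'
        )
        parts.append(
            f'<line x1="{_f(sx(max(mean - sd, 0)))}" y1="{_f(cy)}" '
            f'x2="{_f(sx(mean + sd))}" y2="{_f(cy)}" stroke="#333333" stroke-width="1"/>'
        )
    parts.append("</g>")
    return "\n".join(parts)


_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ margin: 12px; background: #fafafa; }}
#figure {{ background: #ffffff; border: 1px solid #ddd; display: inline-block; }}
#figure svg {{ cursor: grab; }}
</style>
</head>
<body>
<div id="figure">
{svg}
</div>
<script>
(function () {{
  var svg = document.querySelector('#figure svg');
  var vb = svg.viewBox.baseVal;
  var base = {{x: vb.x, y: vb.y, w: vb.width, h: vb.height}};
  svg.addEventListener('wheel', function (ev) {{
    ev.preventDefault();
    var k = ev.deltaY < 0 ? 0.9 : 1.1;
    var px = vb.x + vb.width * (ev.offsetX / svg.clientWidth);
    var py = vb.y + vb.height * (ev.offsetY / svg.clientHeight);
    vb.x = px - (px - vb.x) * k; vb.y = py - (py - vb.y) * k;
    vb.width *= k; vb.height *= k;
  }});
  var drag = null;
  svg.addEventListener('mousedown', function (ev) {{ drag = [ev.clientX, ev.clientY]; }});
  window.addEventListener('mouseup', function () {{ drag = null; }});
  window.addEventListener('mousemove', function (ev) {{
    if (!drag) return;
    vb.x -= (ev.clientX - drag[0]) * vb.width / svg.clientWidth;
    vb.y -= (ev.clientY - drag[1]) * vb.height / svg.clientHeight;
    drag = [ev.clientX, ev.clientY];
  }});
  svg.addEventListener('dblclick', function () {{
    vb.x = base.x; vb.y = base.y; vb.width = base.w; vb.height = base.h;
  }});
}})();
</script>
</body>
</html>
"""


def _wrap_html(figure: FigureSpec, svg: str) -> str:
    title = figure.layout.get("title") or "RNA isoform figure"
    return _HTML_TEMPLATE.format(title=_esc(title), svg=svg)


# ---------------------------------------------------------------------------
# matplotlib renderer (static png/pdf)
# ---------------------------------------------------------------------------

def _render_matplotlib(figure: FigureSpec, path, format: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon, Rectangle

    lay = figure.layout
    n_rows = max(len(figure.row_labels), 1)
    n_panels = len(figure.panels)
    if n_panels == 1:
        ratios = [1.0]
    else:
        sf = lay["structure_fraction"]
        ratios = [sf] + [(1 - sf) / (n_panels - 1)] * (n_panels - 1)

    fig, axes = plt.subplots(
        1, n_panels,
        figsize=(lay["width"] / 96, (60 + n_rows * lay["row_height"]) / 96),
        sharey=True, gridspec_kw={"width_ratios": ratios},
        squeeze=False,
    )
    axes = axes[0]
    for ax, panel in zip(axes, figure.panels):
        ax.set_title(panel.title, fontsize=lay["font_size"] + 1)
        lo, hi = _panel_xrange(panel)
        ax.set_xlim(lo, hi)
        if panel.kind == "structure":
            for s in panel.shapes:
                if s.kind == "rect":
                    ax.add_patch(Rectangle(
                        (s.x_start, s.row - s.height / 2),
                        s.x_end - s.x_start, s.height,
                        facecolor=s.fill_color, edgecolor="#333333",
                        linewidth=s.line_width,
                    ))
                else:
                    ax.plot(
                        [s.x_start, s.x_end], [s.row - s.height, s.row],
                        color=s.fill_color, linewidth=s.line_width, zorder=1,
                    )
        else:
            groups: list[str] = []
            for g in panel.glyphs:
                if g.group_label not in groups:
                    groups.append(g.group_label)
            slot = 0.72 / max(len(groups), 1)
            for g in panel.glyphs:
                gi = groups.index(g.group_label)
                cy = g.row - 0.36 + (gi + 0.5) * slot
                gh = slot * 0.8
                if g.style == "box":
                    st = _box_stats(g.values)
                    ax.plot([st.lo_whisker, st.hi_whisker], [cy, cy], color="#333333", lw=1)
                    ax.add_patch(Rectangle(
                        (st.q1, cy - gh / 2), max(st.q3 - st.q1, (hi - lo) * 1e-3), gh,
                        facecolor=g.fill_color, edgecolor="#333333", lw=1,
                    ))
                    ax.plot([st.median, st.median], [cy - gh / 2, cy + gh / 2],
                            color="#333333", lw=1.5)
                elif g.style == "violin":
                    outline = _violin_outline(g.values)
                    upper = [(v, cy - w * gh / 2) for v, w in outline]
                    lower = [(v, cy + w * gh / 2) for v, w in reversed(outline)]
                    ax.add_patch(Polygon(upper + lower, facecolor=g.fill_color,
                                         edgecolor="#333333", alpha=0.7))
                else:
                    mean = sum(g.values) / len(g.values)
                    sd = float(np.std(np.asarray(g.values)))
                    ax.add_patch(Rectangle((0, cy - gh / 2), mean, gh,
                                           facecolor=g.fill_color, edgecolor="#333333"))
                    ax.plot([max(mean - sd, 0), mean + sd], [cy, cy], color="#333333", lw=1)
    axes[0].set_ylim(n_rows - 0.5, -0.5)  # inverted: row 0 on top
    axes[0].set_yticks(range(len(figure.row_labels)))
    axes[0].set_yticklabels(figure.row_labels, fontsize=lay["font_size"])
    if lay["title"]:
        fig.suptitle(lay["title"])
    fig.tight_layout()
    fig.savefig(path, format=format, dpi=150)
    plt.close(fig)
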