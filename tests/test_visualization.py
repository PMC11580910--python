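"""Trace construction, panel composition, and figure export."""

import xml.etree.ElementTree as ET

import pandas as pd
import pytest

from conftest import make_annotation
from isoviz.errors import ConfigurationError, SynchronizationError, ValidationError
from isoviz.figure import export, make_plot, render_svg
from isoviz.rescale import shorten_gaps
from isoviz.structure import calculate_exon_number, to_intron
from isoviz.traces import make_traces, shape_counts


def two_exon_annotation(with_cds=False):
    rows = [{"start": 100, "end": 200}, {"start": 500, "end": 600}]
    if with_cds:
        rows += [
            {"start": 150, "end": 200, "feature_type": "CDS"},
            {"start": 500, "end": 550, "feature_type": "CDS"},
        ]
    return to_intron(make_annotation(rows))


def long_expression(tx_ids, groups=("AD", "CT"), n_per_group=3):
    rows = []
    for tx in tx_ids:
        for g in groups:
            for i in range(n_per_group):
                rows.append({"sample_id": f"{g}{i}", "transcript_id": tx,
                             "counts": 10.0 + i, "group": g})
    return pd.DataFrame(rows)


class TestMakeTraces:
    def test_two_exon_transcript_shape_census(self):
        traces = make_traces(two_exon_annotation())
        counts = shape_counts(traces)
        assert counts == {0: {"rect": 2, "line": 1}}

    def test_cds_segments_add_rects_not_lines(self):
        traces = make_traces(two_exon_annotation(with_cds=True))
        assert shape_counts(traces) == {0: {"rect": 4, "line": 1}}
        heights = sorted({s.height for s in traces.structure_shapes if s.kind == "rect"})
        assert heights == [0.30, 0.50]  # exon thin, CDS dominant

    def test_glyph_enumeration_per_transcript_and_group(self, make_gene):
        table, _ = make_gene(seed=8, n_transcripts=5)
        ann = to_intron(table)
        tx = list(dict.fromkeys(ann["transcript_id"]))
        traces = make_traces(ann, long_expression(tx), style={"group_by": "group"})
        assert len(traces.expression_glyphs) == 5 * 2
        assert traces.group_labels == ["AD", "CT"]

    def test_shape_count_formula_on_fixtures(self, make_gene):
        for seed in range(10):
            table, _ = make_gene(seed=seed, n_transcripts=4)
            ann = calculate_exon_number(to_intron(table))
            traces = make_traces(ann)
            counts = shape_counts(traces)
            for tx, row in {t: i for i, t in
                            enumerate(dict.fromkeys(ann["transcript_id"]))}.items():
                grp = ann[ann["transcript_id"] == tx]
                n_body = (grp["feature_type"].isin(["exon", "CDS"])).sum()
                n_intron = (grp["feature_type"] == "intron").sum()
                assert counts[row]["rect"] == n_body
                assert counts[row]["line"] == n_intron

    def test_multiple_genes_rejected(self):
        ann = pd.concat([
            make_annotation([{"gene_id": "A"}]),
            make_annotation([{"gene_id": "B", "transcript_id": "T2"}]),
        ], ignore_index=True)
        with pytest.raises(ValidationError, match="one gene"):
            make_traces(ann)

    def test_stray_expression_transcripts_rejected(self):
        with pytest.raises(SynchronizationError, match="T9"):
            make_traces(two_exon_annotation(), long_expression(["T9"]))

    def test_hover_reports_genomic_coordinates_after_rescaling(self, make_gene):
        table, _ = make_gene(seed=1, n_transcripts=3)
        ann = shorten_gaps(calculate_exon_number(to_intron(table)), 50)
        traces = make_traces(ann)
        by_key = {(r["transcript_id"], r["feature_type"], r["start"]): r
                  for _, r in ann.iterrows()}
        for shape in traces.structure_shapes:
            # every hover text cites a genomic interval present in the table
            coord = shape.hover_text.split("|")[-1].strip()
            span = coord.split(" ")[0].split(":")[1]
            gstart, gend = map(int, span.split("-"))
            match = (ann["genomic_start"] == gstart) & (ann["genomic_end"] == gend)
            assert match.any()
            # display coordinates differ from genomic ones after rescaling,
            # so a genomic-interval hit proves hover is not showing display space
            assert (ann.loc[match, "start"] != gstart).all()


class TestMakePlot:
    def test_structure_only_single_panel(self):
        fig = make_plot(make_traces(two_exon_annotation()))
        assert len(fig.panels) == 1 and fig.panels[0].kind == "structure"

    def test_expression_measures_add_panels_sharing_rows(self, make_gene):
        table, _ = make_gene(seed=8, n_transcripts=5)
        ann = to_intron(table)
        tx = list(dict.fromkeys(ann["transcript_id"]))
        expr = long_expression(tx)
        expr["cpm"] = expr["counts"] * 10
        expr["relative_abundance"] = 5.0
        traces = make_traces(ann, expr, style={
            "group_by": "group",
            "measures": ["counts", "cpm", "relative_abundance"],
        })
        fig = make_plot(traces)
        assert [p.kind for p in fig.panels] == ["structure"] + ["expression"] * 3
        assert fig.shared_row_axis
        # identical row order in every panel: a single shared label list
        assert fig.row_labels == traces.row_labels

    def test_missing_measure_panel_rejected(self):
        traces = make_traces(two_exon_annotation())
        with pytest.raises(ConfigurationError, match="cpm"):
            make_plot(traces, layout={"measures": ["cpm"]})


class TestExport:
    @pytest.fixture
    def figure(self, make_gene):
        table, _ = make_gene(seed=8, n_transcripts=4)
        ann = shorten_gaps(calculate_exon_number(to_intron(table)), 100)
        tx = list(dict.fromkeys(ann["transcript_id"]))
        traces = make_traces(ann, long_expression(tx), style={"group_by": "group"})
        return make_plot(traces)

    def test_html_is_self_contained(self, figure, tmp_path):
        out = tmp_path / "fig.html"
        export(figure, out, "html")
        text = out.read_text()
        assert out.stat().st_size > 0
        assert "<svg" in text and "</html>" in text
        for marker in ("http://", "https://", "src="):
            assert marker not in text.replace("http://www.w3.org/2000/svg", "")

    def test_svg_parses_as_valid_xml(self, figure, tmp_path):
        out = tmp_path / "fig.svg"
        export(figure, out, "svg")
        root = ET.parse(out).getroot()
        assert root.tag.endswith("svg")

    @pytest.mark.parametrize("fmt", ["png", "pdf"])
    def test_static_exports_written(self, figure, tmp_path, fmt):
        out = tmp_path / f"fig.{fmt}"
        export(figure, out, fmt)
        assert out.stat().st_size > 0

    def test_html_payload_deterministic(self, make_gene, tmp_path):
        paths = []
        for i in (1, 2):
            table, _ = make_gene(seed=8, n_transcripts=4)
            ann = shorten_gaps(calculate_exon_number(to_intron(table)), 100)
            traces = make_traces(ann)
            p = tmp_path / f"fig{i}.html"
            export(make_plot(traces), p, "html")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_unsupported_format_rejected(self, figure, tmp_path):
        with pytest.raises(ConfigurationError, match="format"):
            export(figure, tmp_path / "f.bmp", "bmp")

    def test_unwritable_path_raises_oserror(self, figure, tmp_path):
        with pytest.raises(OSError):
            export(figure, tmp_path / "nodir" / "f.svg", "svg")

    def test_svg_row_labels_in_order(self, figure):
        svg = render_svg(figure)
        positions = [svg.index(label) for label in figure.row_labels]
        assert positions == sorted(positions)
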