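"""Gene filtering, intron derivation, strand-aware exon numbering."""

import pandas as pd
import pytest

from conftest import make_annotation
from isoviz.errors import ConfigurationError, GeneNotFoundError, ValidationError
from isoviz.structure import calculate_exon_number, gene_filtering, to_intron


def three_exon_transcript(strand="+", tx="T1"):
    return make_annotation([
        {"start": s, "end": e, "strand": strand, "transcript_id": tx,
         "transcript_name": tx + "n"}
        for s, e in [(100, 200), (300, 400), (500, 600)]
    ])


def long_expression(counts_by_tx):
    rows = []
    for tx, per_sample in counts_by_tx.items():
        for i, c in enumerate(per_sample):
            rows.append({"sample_id": f"S{i}", "transcript_id": tx, "counts": c})
    return pd.DataFrame(rows)


class TestGeneFiltering:
    def two_gene_annotation(self):
        return make_annotation([
            {"gene_id": "A", "gene_name": "ALPHA", "transcript_id": "a1"},
            {"gene_id": "B", "gene_name": "BETA", "transcript_id": "b1"},
        ])

    def test_filters_to_target_gene_by_id_or_name(self):
        ann = self.two_gene_annotation()
        for key in ("A", "ALPHA"):
            out, _ = gene_filtering(ann, None, gene=key)
            assert set(out["gene_id"]) == {"A"}

    def test_unknown_gene_lists_near_matches(self):
        with pytest.raises(GeneNotFoundError, match="ALPHA"):
            gene_filtering(self.two_gene_annotation(), None, gene="ALPH")

    def test_ranking_and_top_n_synchronize_outputs(self):
        ann = make_annotation([
            {"transcript_id": t, "start": 100 * i + 1, "end": 100 * i + 50}
            for i, t in enumerate(["t1", "t2", "t3"])
        ])
        expr = long_expression({"t1": [5, 5], "t2": [15, 15], "t3": [10, 10]})
        out_ann, out_expr = gene_filtering(
            ann, expr, gene="G1", order_by_expression=True, keep_top_n=2
        )
        assert list(dict.fromkeys(out_ann["transcript_id"])) == ["t2", "t3"]
        assert set(out_expr["transcript_id"]) == {"t2", "t3"}

    def test_rank_ties_break_lexicographically(self):
        ann = make_annotation([
            {"transcript_id": t} for t in ["tz", "ta", "tm"]
        ])
        expr = long_expression({"tz": [7], "ta": [7], "tm": [7]})
        out_ann, _ = gene_filtering(ann, expr, gene="G1", order_by_expression=True)
        assert list(dict.fromkeys(out_ann["transcript_id"])) == ["ta", "tm", "tz"]

    def test_idempotent(self):
        ann = self.two_gene_annotation()
        once, _ = gene_filtering(ann, None, gene="A")
        twice, _ = gene_filtering(once, None, gene="A")
        pd.testing.assert_frame_equal(once, twice)

    def test_bad_top_n_and_missing_expression(self):
        ann = self.two_gene_annotation()
        with pytest.raises(ConfigurationError):
            gene_filtering(ann, long_expression({"a1": [1]}), gene="A", keep_top_n=0)
        with pytest.raises(ConfigurationError):
            gene_filtering(ann, None, gene="A", keep_top_n=1)


class TestToIntron:
    def test_intron_coordinates_use_abutment_convention(self):
        out = to_intron(three_exon_transcript())
        introns = out[out["feature_type"] == "intron"]
        assert sorted(zip(introns["start"], introns["end"])) == [(200, 300), (400, 500)]
        assert (introns["transcript_id"] == "T1").all()
        assert (introns["strand"] == "+").all()

    def test_single_exon_transcript_yields_no_intron(self):
        ann = make_annotation([{"start": 10, "end": 90}])
        out = to_intron(ann)
        assert (out["feature_type"] == "exon").all() and len(out) == 1

    def test_overlapping_exons_rejected_naming_transcript(self):
        ann = make_annotation([
            {"start": 100, "end": 300}, {"start": 200, "end": 400},
        ])
        with pytest.raises(ValidationError, match="T1"):
            to_intron(ann)

    def test_abutting_exons_yield_no_intron(self):
        ann = make_annotation([{"start": 100, "end": 200}, {"start": 201, "end": 300}])
        out = to_intron(ann)
        assert not (out["feature_type"] == "intron").any()

    def test_per_base_intron_coverage(self, make_gene):
        """Every base strictly between consecutive exon boundaries lies in
        exactly one intron of that transcript."""
        for seed in range(20):
            table, _ = make_gene(seed=seed, n_transcripts=5,
                                 intron_width_range=(2, 60),
                                 exon_width_range=(5, 30))
            out = to_intron(table)
            for tx, grp in out.groupby("transcript_id"):
                exons = grp[grp["feature_type"] == "exon"].sort_values("start")
                introns = grp[grp["feature_type"] == "intron"]
                assert len(introns) == len(exons) - 1
                expected_bases = set()
                rows = exons.to_dict("records")
                for up, down in zip(rows, rows[1:]):
                    expected_bases |= set(range(up["end"] + 1, down["start"]))
                covered = []
                for _, i in introns.iterrows():
                    covered.extend(range(i["start"] + 1, i["end"]))
                assert len(covered) == len(set(covered))  # no double cover
                assert set(covered) == expected_bases


class TestExonNumbering:
    @pytest.mark.parametrize("strand, expected", [("+", [1, 2, 3]), ("-", [3, 2, 1])])
    def test_exons_numbered_by_strand(self, strand, expected):
        out = calculate_exon_number(three_exon_transcript(strand=strand))
        exons = out[out["feature_type"] == "exon"].sort_values("start")
        assert list(exons["exon_number"]) == expected

    def test_existing_numbers_are_overwritten(self):
        ann = three_exon_transcript()
        ann["exon_number"] = [9, 9, 9]
        out = calculate_exon_number(ann)
        assert list(out.sort_values("start")["exon_number"]) == [1, 2, 3]

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_cds_inherits_overlapping_exon_number(self, strand):
        ann = pd.concat([
            three_exon_transcript(strand=strand),
            make_annotation([{"start": 320, "end": 380, "strand": strand,
                              "feature_type": "CDS"}]),
        ], ignore_index=True)
        out = calculate_exon_number(ann)
        cds = out[out["feature_type"] == "CDS"].iloc[0]
        middle = out[(out["feature_type"] == "exon") & (out["start"] == 300)].iloc[0]
        assert cds["exon_number"] == middle["exon_number"]

    def test_cds_overlapping_zero_or_two_exons_rejected(self):
        base = three_exon_transcript()
        orphan = pd.concat([base, make_annotation(
            [{"start": 210, "end": 290, "feature_type": "CDS"}])], ignore_index=True)
        with pytest.raises(ValidationError, match="no exon"):
            calculate_exon_number(orphan)
        spanning = pd.concat([base, make_annotation(
            [{"start": 150, "end": 350, "feature_type": "CDS"}])], ignore_index=True)
        with pytest.raises(ValidationError, match="2 exons"):
            calculate_exon_number(spanning)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_intron_numbers_enumerate_1_to_n_minus_1(self, strand, make_gene):
        for seed in range(10):
            table, _ = make_gene(seed=seed, strand=strand, n_transcripts=4)
            out = calculate_exon_number(to_intron(table))
            for tx, grp in out.groupby("transcript_id"):
                n = (grp["feature_type"] == "exon").sum()
                exon_nums = sorted(grp.loc[grp["feature_type"] == "exon", "exon_number"])
                assert exon_nums == list(range(1, n + 1))
                intron_nums = sorted(grp.loc[grp["feature_type"] == "intron", "exon_number"])
                assert intron_nums == list(range(1, n))

    def test_numbers_match_generator_ground_truth(self, make_gene):
        for strand in ("+", "-"):
            table, truth = make_gene(seed=3, strand=strand, n_transcripts=3)
            out = calculate_exon_number(to_intron(table))
            truth_df = pd.DataFrame(truth)
            key = ["transcript_id", "feature_type", "start", "end"]
            merged = out.merge(truth_df[key + ["exon_number"]], on=key,
                               suffixes=("", "_true"))
            assert len(merged) == len(truth_df)
            assert (merged["exon_number"] == merged["exon_number_true"]).all()
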