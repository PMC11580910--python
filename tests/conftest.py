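import pandas as pd
import pytest

from isoviz.fixtures import SyntheticGeneSpec, generate_gene, write_fixture_set


@pytest.fixture
def make_gene():
    """Factory for synthetic gene tables: make_gene(seed=..., **spec_kwargs)."""

    def _make(seed=0, **kwargs):
        spec = SyntheticGeneSpec(seed=seed, **kwargs)
        return generate_gene(spec)

    return _make


@pytest.fixture
def fixture_paths(tmp_path):
    """A matched GTF + TSV count matrix + metadata trio on disk."""
    return write_fixture_set(tmp_path, seed=11)


def annotation_row(**overrides) -> dict:
    """One fully populated annotation row for hand-built tables."""
    row = {
        "seqname": "chr1",
        "start": 100,
        "end": 200,
        "strand": "+",
        "feature_type": "exon",
        "gene_id": "G1",
        "gene_name": "ALPHA",
        "transcript_id": "T1",
        "transcript_name": "ALPHA-201",
        "transcript_biotype": "protein_coding",
        "exon_number": None,
    }
    row.update(overrides)
    return row


def make_annotation(rows) -> pd.DataFrame:
    table = pd.DataFrame.from_records([annotation_row(**r) for r in rows])
    table["exon_number"] = table["exon_number"].astype("Int64")
    return table
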