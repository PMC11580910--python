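"""Read and validate ENSEMBL-dialect GTF annotations.

The in-memory annotation table is a plain :class:`pandas.DataFrame` with one
row per genomic feature and the columns listed in :data:`ANNOTATION_COLUMNS`.
Coordinates are kept 1-based inclusive (the GTF convention) throughout; only
the rescaling step produces unitless display coordinates.

Only ``exon`` and ``CDS`` feature rows are retained on load; ``intron`` rows
are derived later from exons (see :func:`isoviz.structure.to_intron`).
"""

from __future__ import annotations

import gzip
import io
import re
from pathlib import Path

import pandas as pd

from .errors import EmptyAnnotationError, FormatError, ValidationError

#: Column contract for annotation tables.
ANNOTATION_COLUMNS = [
    "seqname",
    "start",
    "end",
    "strand",
    "feature_type",
    "gene_id",
    "gene_name",
    "transcript_id",
    "transcript_name",
    "transcript_biotype",
    "exon_number",
]

#: Feature types retained from a GTF file.
KEPT_FEATURES = ("exon", "CDS")

_GZIP_MAGIC = b"\x1f\x8b"

_ATTR_RE = re.compile(r'^\s*(\S+)\s+"([^"]*)"\s*$')


def parse_attributes(attribute_field: str) -> dict[str, str]:
    """Parse a GTF column-9 attribute string into a key→value mapping.

    The dialect is a semicolon-separated sequence of ``key "value"`` pairs,
    tolerating a trailing semicolon and variable spacing.  Duplicate keys keep
    the first occurrence; values are returned unquoted.

    Raises
    ------
    FormatError
        If a non-empty token carries no quoted value.
    """
    out: dict[str, str] = {}
    for token in attribute_field.split(";"):
        if not token.strip():
            continue
        m = _ATTR_RE.match(token)
        if m is None:
            raise FormatError(f"malformed attribute token: {token.strip()!r}")
        key, value = m.group(1), m.group(2)
        if key not in out:
            out[key] = value
    return out


def serialize_attributes(attributes: dict[str, str]) -> str:
    """Inverse of :func:`parse_attributes` (used by the fixture writers)."""
    return " ".join(f'{k} "{v}";' for k, v in attributes.items())


def _open_maybe_gzip(path: Path) -> io.TextIOBase:
    # Detect gzip by magic bytes, not extension, so renamed files still load.
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read an ENSEMBL GTF file into an annotation table.

    Only ``exon`` and ``CDS`` rows are kept.  Attribute keys ``gene_id``,
    ``gene_name``, ``transcript_id``, ``transcript_name``,
    ``transcript_biotype`` and ``exon_number`` are lifted into columns;
    missing names are filled from the corresponding identifiers and a missing
    biotype becomes an empty string.  Gzip-compressed input is accepted
    transparently.

    Parameters
    ----------
    path
        A GTF file: tab-separated, nine columns per data line, ``#`` comments.

    Returns
    -------
    pandas.DataFrame
        With the :data:`ANNOTATION_COLUMNS` columns; ``exon_number`` is a
        nullable integer (absent where the file carries none).

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FormatError
        If a data line does not have exactly nine tab-separated fields.
    ValidationError
        If a retained row lacks ``gene_id``/``transcript_id``, has a strand
        outside ``{+,-}``, or has start > end.
    EmptyAnnotationError
        If no exon/CDS rows remain after filtering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")

    records: list[dict] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            seqname, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in KEPT_FEATURES:
                continue
            attributes = parse_attributes(attrs)
            if "gene_id" not in attributes or "transcript_id" not in attributes:
                raise ValidationError(
                    f"line {lineno}: {feature} row lacks gene_id or transcript_id"
                )
            # Tolerate a typographic minus sign for the reverse strand.
            strand = strand.replace("−", "-")
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"line {lineno}: strand must be '+' or '-', got {strand!r}"
                )
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinate") from exc
            if start_i > end_i:
                raise ValidationError(f"line {lineno}: start {start_i} > end {end_i}")
            exon_number = attributes.get("exon_number")
            records.append(
                {
                    "seqname": seqname,
                    "start": start_i,
                    "end": end_i,
                    "strand": strand,
                    "feature_type": feature,
                    "gene_id": attributes["gene_id"],
                    "gene_name": attributes.get("gene_name", ""),
                    "transcript_id": attributes["transcript_id"],
                    "transcript_name": attributes.get("transcript_name", ""),
                    "transcript_biotype": attributes.get("transcript_biotype", ""),
                    "exon_number": int(exon_number) if exon_number is not None else None,
                }
            )

    if not records:
        raise EmptyAnnotationError(
            "no rows remained after keeping only 'exon' and 'CDS' feature types"
        )
    table = pd.DataFrame.from_records(records, columns=ANNOTATION_COLUMNS)
    table["exon_number"] = table["exon_number"].astype("Int64")
    return fill_missing_names(table)


def fill_missing_names(table: pd.DataFrame) -> pd.DataFrame:
    """Fill empty ``gene_name``/``transcript_name`` from the identifiers.

    Rows already named are left untouched.  Returns a new table.
    """
    table = table.copy()
    for name_col, id_col in (("gene_name", "gene_id"), ("transcript_name", "transcript_id")):
        if name_col not in table.columns:
            table[name_col] = ""
        blank = table[name_col].isna() | (table[name_col].astype(str).str.len() == 0)
        table.loc[blank, name_col] = table.loc[blank, id_col]
    return table


def validate_annotation(table: pd.DataFrame) -> None:
    """Assert the structural invariants of an annotation table.

    Checks coordinate ordering, the feature-type domain, strand consistency
    within each transcript, non-empty names, and exon non-overlap per
    transcript.  Raises :class:`ValidationError` on the first violation.
    """
    if (table["start"] > table["end"]).any():
        bad = table.loc[table["start"] > table["end"]].iloc[0]
        raise ValidationError(f"start > end for a row of transcript {bad['transcript_id']}")
    bad_types = set(table["feature_type"]) - {"exon", "CDS", "intron"}
    if bad_types:
        raise ValidationError(f"unexpected feature types: {sorted(bad_types)}")
    strands = table.groupby("transcript_id")["strand"].nunique()
    mixed = strands[strands > 1]
    if len(mixed):
        raise ValidationError(f"mixed strands within transcript {mixed.index[0]}")
    for col in ("gene_name", "transcript_name"):
        if (table[col].astype(str).str.len() == 0).any():
            raise ValidationError(f"empty {col} present; run fill_missing_names")
    exons = table[table["feature_type"] == "exon"]
    for tx, grp in exons.groupby("transcript_id"):
        grp = grp.sort_values("start")
        prev_end = None
        for _, row in grp.iterrows():
            if prev_end is not None and row["start"] <= prev_end:
                raise ValidationError(f"overlapping exons in transcript {tx}")
            prev_end = row["end"]
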