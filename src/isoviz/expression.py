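"""Load expression matrices and compute CPM and relative transcript abundance.

Expression data live in a long-format :class:`pandas.DataFrame` with one row
per (sample, transcript) pair, a ``counts`` column, optional ``cpm`` and
``relative_abundance`` columns, and any sample-metadata columns merged in.

CPM (counts per million) rescales every sample to a library size of one
million: ``cpm = counts / library_size * 1e6`` where the library size is the
sum of counts over *all* transcripts of the loaded matrix — computed before
any gene filtering, since CPM is a library-level normalization.  Relative
transcript abundance is a transcript's percentage share of its gene's total
counts within a sample (isoform usage), in [0, 100].
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, MergeError, UnsupportedFormatError, ValidationError

logger = logging.getLogger(__name__)

_READERS = {
    ".tsv": lambda p: pd.read_csv(p, sep="\t"),
    ".txt": lambda p: pd.read_csv(p, sep="\t"),
    ".csv": pd.read_csv,
    ".xlsx": pd.read_excel,
    ".parquet": pd.read_parquet,
}

_WRITERS = {
    ".tsv": lambda df, p: df.to_csv(p, sep="\t", index=False),
    ".txt": lambda df, p: df.to_csv(p, sep="\t", index=False),
    ".csv": lambda df, p: df.to_csv(p, index=False),
    ".xlsx": lambda df, p: df.to_excel(p, index=False),
    ".parquet": lambda df, p: df.to_parquet(p, index=False),
}


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a tabular file, format inferred from the extension."""
    path = Path(path)
    reader = _READERS.get(path.suffix.lower())
    if reader is None:
        raise UnsupportedFormatError(
            f"unsupported tabular format {path.suffix!r}; "
            f"expected one of {sorted(_READERS)}"
        )
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return reader(path)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame, format inferred from the extension."""
    path = Path(path)
    writer = _WRITERS.get(path.suffix.lower())
    if writer is None:
        raise UnsupportedFormatError(
            f"unsupported tabular format {path.suffix!r}; "
            f"expected one of {sorted(_WRITERS)}"
        )
    writer(table, path)


def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path | None = None,
    *,
    sample_id_column: str = "sample_id",
    transcript_id_column: str = "transcript_id",
    gene_id_column: str | None = None,
    compute_cpm: bool = False,
    compute_relative_abundance: bool = False,
) -> pd.DataFrame:
    """Load an expression matrix (wide or long) into a long-format table.

    A matrix is treated as wide when the transcript-identifier column exists
    and every other non-identifier column is numeric (one column per sample);
    otherwise it must already be long with *sample_id_column* and a ``counts``
    column.  Sample metadata, when given, is merged on *sample_id_column*:
    every matrix sample must have a metadata row (strict), while metadata rows
    for unknown samples are dropped with a logged count (permissive).

    Raises
    ------
    UnsupportedFormatError
        Unknown file extension.
    MergeError
        Matrix samples absent from the metadata, listed in the message.
    ConfigurationError
        ``compute_relative_abundance`` without *gene_id_column*.
    ValidationError
        Negative counts, or a matrix in neither recognized orientation.
    """
    if compute_relative_abundance and gene_id_column is None:
        raise ConfigurationError(
            "compute_relative_abundance requires a gene identifier column"
        )
    matrix = read_table(matrix_path)

    id_columns = [transcript_id_column]
    if gene_id_column is not None and gene_id_column in matrix.columns:
        id_columns.append(gene_id_column)

    long = _to_long(matrix, id_columns, sample_id_column, transcript_id_column)

    if (long["counts"] < 0).any():
        raise ValidationError("negative counts in expression matrix")

    dup = long.duplicated([sample_id_column, transcript_id_column])
    if dup.any():
        raise ValidationError("duplicate (sample, transcript) pairs in expression matrix")

    if metadata_path is not None:
        metadata = read_table(metadata_path)
        if sample_id_column not in metadata.columns:
            raise ConfigurationError(
                f"metadata lacks sample identifier column {sample_id_column!r}"
            )
        matrix_samples = set(long[sample_id_column])
        meta_samples = set(metadata[sample_id_column])
        missing = sorted(matrix_samples - meta_samples)
        if missing:
            raise MergeError(f"samples missing from metadata: {', '.join(missing)}")
        extra = len(meta_samples - matrix_samples)
        if extra:
            logger.info("dropping %d metadata rows for samples not in the matrix", extra)
            metadata = metadata[metadata[sample_id_column].isin(matrix_samples)]
        long = long.merge(metadata, on=sample_id_column, how="left")

    # Normalize the identifier column names to the package-wide contract.
    rename = {sample_id_column: "sample_id", transcript_id_column: "transcript_id"}
    if gene_id_column is not None and gene_id_column in long.columns:
        rename[gene_id_column] = "gene_id"
    long = long.rename(columns=rename)

    if compute_cpm:
        long = cpm_normalize(long)
    if compute_relative_abundance:
        long = relative_abundance(long)
    return long.reset_index(drop=True)


def _to_long(
    matrix: pd.DataFrame,
    id_columns: list[str],
    sample_id_column: str,
    transcript_id_column: str,
) -> pd.DataFrame:
    if transcript_id_column not in matrix.columns:
        raise ValidationError(
            f"matrix lacks transcript identifier column {transcript_id_column!r}"
        )
    value_columns = [c for c in matrix.columns if c not in id_columns]
    is_wide = len(value_columns) > 0 and all(
        pd.api.types.is_numeric_dtype(matrix[c]) for c in value_columns
    )
    if is_wide:
        return matrix.melt(
            id_vars=id_columns,
            value_vars=value_columns,
            var_name=sample_id_column,
            value_name="counts",
        )
    if sample_id_column in matrix.columns and "counts" in matrix.columns:
        return matrix.copy()
    raise ValidationError(
        "matrix is neither wide (all non-identifier columns numeric) nor "
        f"long (columns {sample_id_column!r} and 'counts' present)"
    )


def cpm_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``cpm`` column: counts scaled to a per-sample library of 1e6.

    A sample with zero library size gets cpm 0 everywhere and a warning; NaN
    never appears (downstream glyphs must stay renderable).
    """
    table = table.copy()
    library = table.groupby("sample_id")["counts"].transform("sum")
    zero = library == 0
    if zero.any():
        samples = sorted(table.loc[zero, "sample_id"].unique())
        warnings.warn(
            f"zero library size for sample(s) {', '.join(map(str, samples))}; cpm set to 0",
            stacklevel=2,
        )
    table["cpm"] = 0.0
    table.loc[~zero, "cpm"] = table.loc[~zero, "counts"] / library[~zero] * 1e6
    return table


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``relative_abundance``: % of the gene's counts per sample.

    Genes with zero total counts in a sample get 0 for all their transcripts.
    """
    if "gene_id" not in table.columns or table["gene_id"].isna().any():
        raise ConfigurationError("relative_abundance requires gene_id on every row")
    table = table.copy()
    gene_total = table.groupby(["sample_id", "gene_id"])["counts"].transform("sum")
    zero = gene_total == 0
    table["relative_abundance"] = 0.0
    table.loc[~zero, "relative_abundance"] = (
        table.loc[~zero, "counts"] / gene_total[~zero] * 100.0
    )
    return table
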