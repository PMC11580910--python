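"""Structural transforms: gene filtering, intron derivation, exon numbering.

All three operate on the annotation-table contract defined in
:mod:`isoviz.annotation` (1-based inclusive coordinates, ``feature_type`` in
{exon, CDS, intron}).
"""

from __future__ import annotations

import difflib

import pandas as pd

from .errors import ConfigurationError, GeneNotFoundError, ValidationError

#: Intron rows narrower than this (end − start ≤ 1) come from genomically
#: abutting exons, contain no intronic base, and are dropped.
_MIN_INTRON_SPAN = 2


def gene_filtering(
    annotation: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    *,
    gene: str,
    order_by_expression: bool = False,
    keep_top_n: int | None = None,
    measure: str = "counts",
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Restrict annotation (and, optionally, expression) to one gene.

    The gene is matched against ``gene_id`` first, then ``gene_name``.  When
    an expression table is supplied it is synchronized to the transcripts
    present in the filtered annotation.  With ``order_by_expression``,
    transcripts are ranked by total *measure* summed over all samples
    (descending, ties broken by transcript_id) and both outputs are reordered
    accordingly; ``keep_top_n`` then truncates to the first *n* ranked
    transcripts in both outputs.

    Raises
    ------
    GeneNotFoundError
        Unknown gene; the error lists nearest-matching identifiers.
    ConfigurationError
        ``keep_top_n`` < 1, or ranking options used without expression data.
    """
    if keep_top_n is not None and keep_top_n < 1:
        raise ConfigurationError(f"keep_top_n must be >= 1, got {keep_top_n}")
    if (order_by_expression or keep_top_n is not None) and expression is None:
        raise ConfigurationError(
            "order_by_expression / keep_top_n need an expression table to rank by"
        )

    mask = annotation["gene_id"] == gene
    if not mask.any():
        mask = annotation["gene_name"] == gene
    if not mask.any():
        universe = sorted(set(annotation["gene_id"]) | set(annotation["gene_name"]))
        raise GeneNotFoundError(gene, difflib.get_close_matches(gene, universe, n=3, cutoff=0.3))
    ann = annotation[mask].copy()

    expr = None
    if expression is not None:
        transcripts = set(ann["transcript_id"])
        expr = expression[expression["transcript_id"].isin(transcripts)].copy()

    if order_by_expression or keep_top_n is not None:
        totals = (
            expr.groupby("transcript_id")[measure]
            .sum()
            .reindex(sorted(set(ann["transcript_id"])), fill_value=0)
        )
        # Descending by total; ties broken lexicographically for determinism.
        ranked = sorted(totals.index, key=lambda t: (-totals[t], t))
        if keep_top_n is not None:
            ranked = ranked[:keep_top_n]
            ann = ann[ann["transcript_id"].isin(ranked)].copy()
            expr = expr[expr["transcript_id"].isin(ranked)].copy()
        order = {t: i for i, t in enumerate(ranked)}
        ann = ann.assign(_rank=ann["transcript_id"].map(order)).sort_values(
            ["_rank", "start"], kind="stable"
        ).drop(columns="_rank")
        expr = expr.assign(_rank=expr["transcript_id"].map(order)).sort_values(
            ["_rank", "sample_id"], kind="stable"
        ).drop(columns="_rank")

    return ann.reset_index(drop=True), (expr.reset_index(drop=True) if expr is not None else None)


def to_intron(annotation: pd.DataFrame) -> pd.DataFrame:
    """Derive intron rows from consecutive exons of each transcript.

    Returns the input rows plus one intron row between each pair of
    genomically consecutive exons, using the visual-abutment convention:
    intron start = upstream exon end, intron end = downstream exon start
    (endpoints shared with the flanking exons so rendered shapes abut).
    Introns inherit seqname, strand and gene/transcript identity; per
    transcript the intron count is exon count − 1 (abutting exons, which
    enclose no intronic base, yield no intron).

    Raises
    ------
    ValidationError
        Overlapping exons within one transcript (named in the message).
    """
    introns: list[dict] = []
    exons = annotation[annotation["feature_type"] == "exon"]
    for tx, grp in exons.groupby("transcript_id", sort=False):
        grp = grp.sort_values("start")
        rows = grp.to_dict("records")
        for up, down in zip(rows, rows[1:]):
            if down["start"] <= up["end"]:
                raise ValidationError(f"overlapping exons in transcript {tx}")
            if down["start"] - up["end"] < _MIN_INTRON_SPAN:
                continue  # abutting exons: no intronic base
            intron = dict(up)
            intron.update(
                start=up["end"],
                end=down["start"],
                feature_type="intron",
                exon_number=None,
            )
            introns.append(intron)
    if not introns:
        return annotation.copy()
    intron_df = pd.DataFrame.from_records(introns)[annotation.columns.tolist()]
    intron_df["exon_number"] = intron_df["exon_number"].astype("Int64")
    out = pd.concat([annotation, intron_df], ignore_index=True)
    out["exon_number"] = out["exon_number"].astype("Int64")
    return out


def calculate_exon_number(annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign exon numbers to exons, CDS and introns, strand-aware.

    Exons are numbered 1..n in transcription (5′→3′) order: ascending genomic
    start on the plus strand, descending on the minus strand.  Each CDS row
    takes the number of the single exon it overlaps; each intron takes the
    number of its 5′-flanking exon in transcription order, so a transcript's
    introns carry exactly {1..n−1} on either strand.  Existing exon_number
    values are overwritten.

    Raises
    ------
    ValidationError
        A CDS overlapping zero or more than one exon of its transcript, or a
        transcript with intron/CDS rows but no exons.
    """
    annotation = annotation.copy()
    numbers = pd.Series(pd.NA, index=annotation.index, dtype="Int64")

    for tx, grp in annotation.groupby("transcript_id", sort=False):
        ex = grp[grp["feature_type"] == "exon"].sort_values("start")
        if ex.empty:
            raise ValidationError(f"transcript {tx} has no exon rows to number")
        strand = ex["strand"].iloc[0]
        n = len(ex)
        # Genomic-order index i (0-based, ascending start) → exon number.
        def exon_no(i: int) -> int:
            return i + 1 if strand == "+" else n - i

        starts = ex["start"].to_numpy()
        ends = ex["end"].to_numpy()
        for i, idx in enumerate(ex.index):
            numbers[idx] = exon_no(i)

        for idx, row in grp[grp["feature_type"] == "CDS"].iterrows():
            hits = [
                i for i in range(n)
                if row["start"] <= ends[i] and row["end"] >= starts[i]
            ]
            if len(hits) == 0:
                raise ValidationError(f"CDS overlaps no exon in transcript {tx}")
            if len(hits) > 1:
                raise ValidationError(
                    f"CDS overlaps {len(hits)} exons in transcript {tx}; "
                    "CDS rows must be per-exon segments"
                )
            numbers[idx] = exon_no(hits[0])

        for idx, row in grp[grp["feature_type"] == "intron"].iterrows():
            # Flanking exons share endpoints with the intron by construction.
            left = [i for i in range(n) if ends[i] == row["start"]]
            right = [i for i in range(n) if starts[i] == row["end"]]
            if not left or not right:
                raise ValidationError(
                    f"intron ({row['start']},{row['end']}) of transcript {tx} "
                    "is not flanked by exons"
                )
            five_prime = left[0] if strand == "+" else right[0]
            numbers[idx] = exon_no(five_prime)

    annotation["exon_number"] = numbers
    return annotation
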