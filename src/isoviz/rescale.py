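"""Intron gap shortening: a global monotone display-coordinate transform.

Long introns dominate a gene's genomic span and squeeze exons into slivers.
The transform here compresses every region that is intronic (or intergenic)
in *all* plotted transcripts down to a target display width, while leaving
exon widths untouched, so exon structure becomes legible.

The map is built once from the union of all exon intervals across all
transcripts: union blocks keep their width, the complement gaps between them
are clamped to ``target_gap_width``, and rescaled starts accumulate left to
right from 0 (the global minimum exon start maps to 0).  Because one global
map is applied to every transcript, exons identical in genomic coordinates
stay aligned across transcripts, and the region upstream of a transcript's
first exon (its start gap) is compressed by the same rule.

Display coordinates are unitless.  Width is ``end − start`` in both spaces;
compression clamps whole gap segments (within a compressed gap the first
``target_gap_width`` units map identically and the remainder collapses onto
the gap's right edge — no proportional scaling), which keeps the map exactly
equal to a per-integer-coordinate remapping oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, EmptyAnnotationError, ValidationError

#: Default compressed width of a gap, in display units.
DEFAULT_TARGET_GAP_WIDTH = 100


@dataclass(frozen=True)
class Segment:
    """One piece of the piecewise map, in original and display coordinates."""

    original_start: int
    original_end: int
    rescaled_start: float
    rescaled_width: float
    is_gap: bool

    @property
    def original_width(self) -> int:
        return self.original_end - self.original_start


@dataclass
class CoordinateMap:
    """Monotone original→display mapping built from exon-union blocks.

    ``blocks`` tile the original span [global_min_start, global_max_end]:
    exon-union segments keep their width; gap segments get
    ``min(width, target_gap_width)``.
    """

    blocks: list[Segment] = field(default_factory=list)
    target_gap_width: int = DEFAULT_TARGET_GAP_WIDTH

    def map_position(self, x: float) -> float:
        """Map one original coordinate into display space.

        Inside a compressed gap, positions beyond the target width collapse
        onto the gap's right edge; everywhere else the map is a pure shift.
        """
        if not self.blocks:
            raise ValueError("empty coordinate map")
        first, last = self.blocks[0], self.blocks[-1]
        if x <= first.original_start:
            return first.rescaled_start - (first.original_start - x)
        if x >= last.original_end:
            return last.rescaled_start + last.rescaled_width + (x - last.original_end)
        for seg in self.blocks:
            if seg.original_start <= x <= seg.original_end:
                offset = x - seg.original_start
                if seg.is_gap:
                    offset = min(offset, seg.rescaled_width)
                return seg.rescaled_start + offset
        raise AssertionError("segments do not tile the span")  # pragma: no cover


def _exon_union(exons: pd.DataFrame) -> list[tuple[int, int]]:
    """Merge exon intervals into disjoint union blocks (abutting merge too)."""
    intervals = sorted(zip(exons["start"], exons["end"]))
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_coordinate_map(
    annotation: pd.DataFrame, target_gap_width: int = DEFAULT_TARGET_GAP_WIDTH
) -> CoordinateMap:
    """Build the global gap-shortening map from an annotation's exon rows.

    Raises
    ------
    ValidationError
        Exons on more than one seqname (one map spans one reference).
    EmptyAnnotationError
        No exon rows to build the union from.
    ConfigurationError
        Non-positive target width.
    """
    if target_gap_width < 1:
        raise ConfigurationError(f"target_gap_width must be >= 1, got {target_gap_width}")
    exons = annotation[annotation["feature_type"] == "exon"]
    if exons.empty:
        raise EmptyAnnotationError("no exon rows to build a coordinate map from")
    if exons["seqname"].nunique() > 1:
        raise ValidationError(
            f"exons span multiple seqnames: {sorted(exons['seqname'].unique())}"
        )

    union = _exon_union(exons)
    blocks: list[Segment] = []
    cursor = 0.0
    prev_end: int | None = None
    for s, e in union:
        if prev_end is not None and s > prev_end:
            gap_w = s - prev_end
            rescaled_w = min(gap_w, target_gap_width)
            blocks.append(Segment(prev_end, s, cursor, rescaled_w, is_gap=True))
            cursor += rescaled_w
        blocks.append(Segment(s, e, cursor, e - s, is_gap=False))
        cursor += e - s
        prev_end = e
    return CoordinateMap(blocks=blocks, target_gap_width=target_gap_width)


def shorten_gaps(
    annotation: pd.DataFrame, target_gap_width: int = DEFAULT_TARGET_GAP_WIDTH
) -> pd.DataFrame:
    """Rescale every row's coordinates through the global gap-shortening map.

    Exon and CDS widths are preserved exactly (they lie inside union blocks);
    intron widths shrink by exactly the compression applied to the gaps they
    span; left-to-right feature order is preserved.  Original genomic
    coordinates are retained in ``genomic_start``/``genomic_end`` companion
    columns so hover text can keep reporting genomic positions.
    """
    cmap = build_coordinate_map(annotation, target_gap_width)
    out = annotation.copy()
    out["genomic_start"] = out["start"]
    out["genomic_end"] = out["end"]
    out["start"] = [cmap.map_position(x) for x in out["genomic_start"]]
    out["end"] = [cmap.map_position(x) for x in out["genomic_end"]]
    return out
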