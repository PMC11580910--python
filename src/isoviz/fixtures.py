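"""Deterministic synthetic annotations, count matrices and metadata.

Everything downstream is testable without downloads: these generators emit
GTF files (plain or gzip), wide count matrices in any supported tabular
format, and sample metadata, together with exact per-row ground truth
(true exon numbers, true intron intervals) for oracle tests.

What the generator emulates: a multi-transcript gene locus with overlapping
isoforms (shared promoter region, variable exon counts/widths, realistic
intron lengths), optional per-exon CDS segments, and negative-binomial-like
counts with a multiplicative group effect on a subset of transcripts — the
shape of a small two-condition isoform-expression experiment.  It does not
emulate splice-site sequences, read-level noise or between-sample library
composition effects.

All randomness flows from a single integer seed through a local
:class:`numpy.random.Generator`; no global state is touched, and equal seeds
give byte-identical output files.
"""

from __future__ import annotations

import gzip as _gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ANNOTATION_COLUMNS, serialize_attributes
from .errors import ConfigurationError
from .expression import write_table


@dataclass
class SyntheticGeneSpec:
    """Parameters of one synthetic gene locus.

    Defaults describe a typical protein-coding human gene drawn small enough
    to plot: a handful of isoforms, exons of 50–300 bp separated by introns
    of 100–2000 bp, most transcripts coding.
    """

    gene_id: str = "GENE1"
    n_transcripts: int = 5
    exon_count_range: tuple[int, int] = (2, 8)
    exon_width_range: tuple[int, int] = (50, 300)
    intron_width_range: tuple[int, int] = (100, 2000)
    strand: str = "+"
    cds_fraction: float = 0.7
    seed: int = 0
    gene_name: str | None = None
    locus_start: int = 10_000

    def __post_init__(self) -> None:
        for name in ("exon_count_range", "exon_width_range", "intron_width_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"impossible geometry: {name}={lo, hi}")
        if self.n_transcripts < 1:
            raise ConfigurationError("n_transcripts must be >= 1")
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.cds_fraction <= 1.0:
            raise ConfigurationError("cds_fraction must be in [0, 1]")


def generate_gene(spec: SyntheticGeneSpec) -> tuple[pd.DataFrame, list[dict]]:
    """Generate one gene's annotation table plus exact ground truth.

    Returns
    -------
    (table, truth)
        *table* is a valid annotation table of exon and CDS rows (exon_number
        filled everywhere — the GTF writer decides which transcripts omit
        it).  *truth* is one record per feature, including derived intron
        intervals and strand-aware exon numbers, for oracle tests.
    """
    rng = np.random.default_rng(spec.seed)
    gene_name = spec.gene_name if spec.gene_name is not None else spec.gene_id + "_NAME"

    rows: list[dict] = []
    truth: list[dict] = []
    for t in range(spec.n_transcripts):
        tx_id = f"{spec.gene_id}.T{t + 1}"
        tx_name = f"{gene_name}-{t + 1:02d}"
        n_exons = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
        # Shared promoter region: transcripts start near the locus start.
        pos = spec.locus_start + int(rng.integers(0, 400))
        exons: list[tuple[int, int]] = []
        for _ in range(n_exons):
            width = int(rng.integers(spec.exon_width_range[0], spec.exon_width_range[1] + 1))
            exons.append((pos, pos + width - 1))  # 1-based inclusive
            pos += width + int(
                rng.integers(spec.intron_width_range[0], spec.intron_width_range[1] + 1)
            )

        n = len(exons)
        numbers = [i + 1 if spec.strand == "+" else n - i for i in range(n)]
        has_cds = rng.random() < spec.cds_fraction and n >= 1

        for i, (s, e) in enumerate(exons):
            base = {
                "seqname": "chrS",
                "strand": spec.strand,
                "gene_id": spec.gene_id,
                "gene_name": gene_name,
                "transcript_id": tx_id,
                "transcript_name": tx_name,
                "transcript_biotype": "protein_coding" if has_cds else "lncRNA",
            }
            rows.append({**base, "start": s, "end": e, "feature_type": "exon",
                         "exon_number": numbers[i]})
            truth.append({**base, "start": s, "end": e, "feature_type": "exon",
                          "exon_number": numbers[i]})
            if has_cds:
                # Per-exon CDS segment, trimmed inside the exon.
                trim_l = int(rng.integers(0, max((e - s) // 3, 1)))
                trim_r = int(rng.integers(0, max((e - s) // 3, 1)))
                cs, ce = s + trim_l, e - trim_r
                if cs <= ce:
                    rows.append({**base, "start": cs, "end": ce, "feature_type": "CDS",
                                 "exon_number": numbers[i]})
                    truth.append({**base, "start": cs, "end": ce, "feature_type": "CDS",
                                  "exon_number": numbers[i]})
            if i + 1 < n:
                # True intron, visual-abutment convention; its exon number is
                # that of the 5'-flanking exon in transcription order.
                istart, iend = e, exons[i + 1][0]
                five_prime = i if spec.strand == "+" else i + 1
                truth.append({**base, "start": istart, "end": iend,
                              "feature_type": "intron",
                              "exon_number": numbers[five_prime]})

    table = pd.DataFrame.from_records(rows, columns=ANNOTATION_COLUMNS)
    table["exon_number"] = table["exon_number"].astype("Int64")
    return table, truth


def write_gtf(
    table: pd.DataFrame,
    path: str | Path,
    *,
    compress: bool = False,
    distractors: bool = True,
    omit_exon_number_seed: int | None = None,
) -> None:
    """Write an annotation table as an ENSEMBL-dialect GTF file.

    With *distractors*, gene and five_prime_utr lines are interleaved to
    exercise the exon/CDS-only loading contract.  With
    *omit_exon_number_seed*, a seeded half of the transcripts is written
    without exon_number attributes (to exercise downstream renumbering).
    """
    path = Path(path)
    omit: set[str] = set()
    if omit_exon_number_seed is not None:
        tx = sorted(set(table["transcript_id"]))
        rng = np.random.default_rng(omit_exon_number_seed)
        omit = set(np.array(tx)[rng.random(len(tx)) < 0.5])

    lines = ["#!genome-build synthetic", "#!genebuild-last-updated 2024-01"]
    for gene_id, grp in table.groupby("gene_id", sort=False):
        if distractors:
            first = grp.iloc[0]
            attrs = {"gene_id": gene_id, "gene_name": first["gene_name"]}
            lines.append(
                "\t".join([
                    first["seqname"], "synthetic", "gene",
                    str(int(grp["start"].min())), str(int(grp["end"].max())),
                    ".", first["strand"], ".", serialize_attributes(attrs),
                ])
            )
        for _, row in grp.iterrows():
            attrs = {
                "gene_id": row["gene_id"],
                "gene_name": row["gene_name"],
                "transcript_id": row["transcript_id"],
                "transcript_name": row["transcript_name"],
                "transcript_biotype": row["transcript_biotype"],
            }
            if not pd.isna(row["exon_number"]) and row["transcript_id"] not in omit:
                attrs["exon_number"] = str(int(row["exon_number"]))
            lines.append(
                "\t".join([
                    row["seqname"], "synthetic", row["feature_type"],
                    str(int(row["start"])), str(int(row["end"])),
                    ".", row["strand"], "." if row["feature_type"] != "CDS" else "0",
                    serialize_attributes(attrs),
                ])
            )
            if distractors and row["feature_type"] == "exon" and row["start"] == table["start"].min():
                utr = dict(attrs)
                lines.append(
                    "\t".join([
                        row["seqname"], "synthetic", "five_prime_utr",
                        str(int(row["start"])), str(int(row["start"]) + 10),
                        ".", row["strand"], ".", serialize_attributes(utr),
                    ])
                )
    text = "\n".join(lines) + "\n"
    if compress:
        with _gzip.open(path, "wt", encoding="utf-8") as fh:
            fh.write(text)
    else:
        path.write_text(text, encoding="utf-8")


#: Multiplicative group effect applied to affected transcripts.
GROUP_EFFECT_SIZE = 3.0
#: Negative-binomial dispersion (number of successes parameter).
NB_DISPERSION = 5.0


def generate_counts(
    transcript_ids: list[str],
    n_samples: int,
    n_groups: int = 1,
    seed: int = 0,
    *,
    effect_size: float = GROUP_EFFECT_SIZE,
    base_mean: float = 200.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a wide count matrix and matching sample metadata.

    Counts are negative-binomial with per-transcript lognormal base means
    around *base_mean*; a seeded half of the transcripts gets its mean
    multiplied by *effect_size* in every group after the first.  Samples are
    assigned to groups evenly (``group_1``, ``group_2``, ...).

    Returns
    -------
    (matrix, metadata, truth)
        *matrix* is wide (transcript_id + one numeric column per sample);
        *metadata* maps sample_id → group; *truth* records the affected
        transcripts and the effect size.
    """
    if not transcript_ids:
        raise ConfigurationError("transcript_ids must be non-empty")
    if not (n_samples >= n_groups >= 1):
        raise ConfigurationError("need n_samples >= n_groups >= 1")

    rng = np.random.default_rng(seed)
    n_tx = len(transcript_ids)
    base = base_mean * rng.lognormal(0.0, 0.8, size=n_tx)
    affected = rng.random(n_tx) < 0.5

    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    groups = [f"group_{i % n_groups + 1}" for i in range(n_samples)]

    data = {}
    for sample, group in zip(samples, groups):
        mu = base.copy()
        if group != "group_1":
            mu[affected] *= effect_size
        p = NB_DISPERSION / (NB_DISPERSION + mu)
        data[sample] = rng.negative_binomial(NB_DISPERSION, p)
    matrix = pd.DataFrame({"transcript_id": transcript_ids, **data})
    metadata = pd.DataFrame({"sample_id": samples, "group": groups})
    truth = {
        "affected_transcripts": [t for t, a in zip(transcript_ids, affected) if a],
        "effect_size": effect_size,
        "base_means": dict(zip(transcript_ids, base)),
    }
    return matrix, metadata, truth


def write_fixture_set(
    out_dir: str | Path,
    *,
    seed: int = 0,
    matrix_format: str = ".tsv",
    n_samples: int = 8,
    n_groups: int = 2,
    gene_spec: SyntheticGeneSpec | None = None,
) -> dict[str, Path]:
    """Write a matched GTF + count matrix + metadata trio to *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = gene_spec if gene_spec is not None else SyntheticGeneSpec(seed=seed)
    table, _ = generate_gene(spec)
    gtf = out_dir / "annotation.gtf"
    write_gtf(table, gtf, omit_exon_number_seed=seed)
    tx_ids = list(dict.fromkeys(table["transcript_id"]))
    matrix, metadata, _ = generate_counts(tx_ids, n_samples, n_groups, seed)
    matrix["gene_id"] = spec.gene_id
    matrix_path = out_dir / f"counts{matrix_format}"
    write_table(matrix, matrix_path)
    meta_path = out_dir / "metadata.tsv"
    write_table(metadata, meta_path)
    return {"gtf": gtf, "matrix": matrix_path, "metadata": meta_path}
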