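"""Readers and writers for the pipeline's tabular formats.

Everything is plain tab-delimited text with a header row:

* SEG-style segment tables: ``sample  chrom  start  end  value``
* mutation tables: the :class:`~clonorigin.core.MutationCall` columns
* gene-CNV tables: ``sample  gene  direction  log2_ratio``
* cohort label tables: ``sample  cancer_type``
* region matrices: ``chrom  start  end`` followed by one column per sample

Coordinates are 1-based inclusive on disk, matching the in-memory
convention; helpers for 0-based half-open (BED-style) conversion are
provided for interoperability but used nowhere internally. Thousands
separators in coordinates (as printed in clinical reports) are stripped
on input and never emitted.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import (
    CnvSegment,
    GeneCnvEvent,
    GenomicInterval,
    MutationCall,
    ValidationError,
    check_segments_disjoint,
    karyotype_sort_key,
)

__all__ = [
    "read_seg",
    "write_seg",
    "read_mutation_table",
    "write_mutation_table",
    "read_gene_cnv_table",
    "write_gene_cnv_table",
    "read_cohort_labels",
    "write_cohort_labels",
    "read_region_matrix",
    "write_region_matrix",
    "to_zero_based_half_open",
    "from_zero_based_half_open",
]

SEG_COLUMNS = ["sample", "chrom", "start", "end", "value"]
MUTATION_COLUMNS = [
    "sample",
    "gene",
    "chrom",
    "position",
    "ref",
    "alt",
    "region_class",
    "allele_frequency",
    "coverage",
    "alt_reads",
    "in_dbsnp",
    "in_germline",
]
GENE_CNV_COLUMNS = ["sample", "gene", "direction", "log2_ratio"]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _coerce_bool(value, *, line: int, column: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(f"line {line}: cannot parse {column}={value!r} as a flag")


def _coerce_int(value, *, line: int, column: str) -> int:
    text = re.sub(r"[,\s]", "", str(value))
    try:
        return int(text)
    except (TypeError, ValueError):
        raise ValidationError(
            f"line {line}: cannot parse {column}={value!r} as an integer"
        ) from None


def _coerce_float(value, *, line: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"line {line}: cannot parse {column}={value!r} as a number"
        ) from None


def _read_table(path, required: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return frame


def read_seg(path) -> list[CnvSegment]:
    """Read a SEG-style table into validated :class:`CnvSegment` records.

    Raises :class:`ValidationError` naming the offending line for
    malformed rows, and naming the offending pair when two segments of
    one sample overlap.
    """
    frame = _read_table(path, SEG_COLUMNS)
    segments = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2  # header is line 1
        interval = GenomicInterval(
            row.chrom,
            _coerce_int(row.start, line=line, column="start"),
            _coerce_int(row.end, line=line, column="end"),
        )
        segments.append(
            CnvSegment(
                sample=str(row.sample),
                interval=interval,
                value=_coerce_float(row.value, line=line, column="value"),
            )
        )
    check_segments_disjoint(segments)
    return segments


def write_seg(segments, path) -> None:
    rows = [
        {
            "sample": s.sample,
            "chrom": s.interval.chromosome,
            "start": s.interval.start,
            "end": s.interval.end,
            "value": s.value,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutation_table(path) -> list[MutationCall]:
    """Read a mutation table; flags are coerced to booleans, records validated."""
    frame = _read_table(path, MUTATION_COLUMNS)
    calls = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2
        try:
            call = MutationCall(
                sample=str(row.sample),
                gene=str(row.gene),
                chromosome=row.chrom,
                position=_coerce_int(row.position, line=line, column="position"),
                ref=str(row.ref),
                alt=str(row.alt),
                region_class=str(row.region_class),
                allele_frequency=_coerce_float(
                    row.allele_frequency, line=line, column="allele_frequency"
                ),
                coverage=_coerce_int(row.coverage, line=line, column="coverage"),
                alt_reads=_coerce_int(row.alt_reads, line=line, column="alt_reads"),
                in_dbsnp=_coerce_bool(row.in_dbsnp, line=line, column="in_dbsnp"),
                in_germline=_coerce_bool(
                    row.in_germline, line=line, column="in_germline"
                ),
            )
        except ValidationError as err:
            raise ValidationError(f"line {line}: {err}") from None
        calls.append(call)
    return calls


def write_mutation_table(calls, path) -> None:
    rows = [
        {
            "sample": c.sample,
            "gene": c.gene,
            "chrom": c.chromosome,
            "position": c.position,
            "ref": c.ref,
            "alt": c.alt,
            "region_class": c.region_class,
            "allele_frequency": c.allele_frequency,
            "coverage": c.coverage,
            "alt_reads": c.alt_reads,
            "in_dbsnp": int(c.in_dbsnp),
            "in_germline": int(c.in_germline),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_cnv_table(path) -> list[GeneCnvEvent]:
    frame = _read_table(path, GENE_CNV_COLUMNS)
    events = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2
        try:
            events.append(
                GeneCnvEvent(
                    sample=str(row.sample),
                    gene=str(row.gene),
                    direction=str(row.direction),
                    log2_ratio=_coerce_float(
                        row.log2_ratio, line=line, column="log2_ratio"
                    ),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"line {line}: {err}") from None
    return events


def write_gene_cnv_table(events, path) -> None:
    rows = [
        {
            "sample": e.sample,
            "gene": e.gene,
            "direction": e.direction,
            "log2_ratio": e.log2_ratio,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=GENE_CNV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cohort_labels(path) -> dict[str, str]:
    """Read a ``sample → cancer_type`` label table into a dict."""
    frame = _read_table(path, ["sample", "cancer_type"])
    labels: dict[str, str] = {}
    for idx, row in enumerate(frame.itertuples(index=False)):
        sample = str(row.sample)
        if sample in labels:
            raise ValidationError(f"line {idx + 2}: duplicate sample {sample!r}")
        labels[sample] = str(row.cancer_type)
    return labels


def write_cohort_labels(labels: Mapping[str, str], path) -> None:
    pd.DataFrame(
        [{"sample": s, "cancer_type": t} for s, t in labels.items()],
        columns=["sample", "cancer_type"],
    ).to_csv(path, sep="\t", index=False)


CNV_INTERVAL_COLUMNS = ["sample", "chrom", "start", "end", "direction"]


def read_cnv_interval_table(path) -> list[tuple[str, GenomicInterval, str]]:
    """Read chromosome-level CNV events: (sample, interval, gain|loss) rows."""
    frame = _read_table(path, CNV_INTERVAL_COLUMNS)
    events = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2
        direction = str(row.direction)
        if direction not in ("gain", "loss"):
            raise ValidationError(
                f"line {line}: direction must be gain or loss, got {direction!r}"
            )
        events.append(
            (
                str(row.sample),
                GenomicInterval(
                    row.chrom,
                    _coerce_int(row.start, line=line, column="start"),
                    _coerce_int(row.end, line=line, column="end"),
                ),
                direction,
            )
        )
    return events


def write_cnv_interval_table(events, path) -> None:
    rows = [
        {
            "sample": sample,
            "chrom": iv.chromosome,
            "start": iv.start,
            "end": iv.end,
            "direction": direction,
        }
        for sample, iv, direction in events
    ]
    pd.DataFrame(rows, columns=CNV_INTERVAL_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_region_matrix(matrix, path) -> None:
    """Write a region × sample matrix: chrom/start/end then one column per sample."""
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_region_matrix(path):
    """Read a region matrix written by :func:`write_region_matrix`."""
    from .regions import RegionMatrix, RegionSet

    frame = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing region column {col!r}")
    regions = [
        GenomicInterval(row.chrom, int(row.start), int(row.end))
        for row in frame.itertuples(index=False)
    ]
    samples = [c for c in frame.columns if c not in ("chrom", "start", "end")]
    values = frame[samples].to_numpy(dtype=float)
    return RegionMatrix(
        region_set=RegionSet(regions), samples=list(samples), values=values
    )


def to_zero_based_half_open(interval: GenomicInterval) -> tuple[str, int, int]:
    """Convert to BED-style (chrom, start0, end_exclusive)."""
    return interval.chromosome, interval.start - 1, interval.end


def from_zero_based_half_open(chrom: str, start0: int, end_excl: int) -> GenomicInterval:
    return GenomicInterval(chrom, start0 + 1, end_excl)


def sort_segments(segments) -> list[CnvSegment]:
    """Sort segments by sample then karyotype order for stable output."""
    return sorted(
        segments,
        key=lambda s: (
            s.sample,
            karyotype_sort_key(s.interval.chromosome),
            s.interval.start,
        ),
    )
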