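"""Multi-sample alignment of segmented copy-number data into disjoint regions.

Different samples are segmented at different breakpoints, so their
profiles cannot be compared column-wise until all segments are cut at
the union of every sample's breakpoints. Per chromosome, every segment
start and every segment end+1 becomes a breakpoint; the maximal
intervals between consecutive breakpoints that are covered by at least
one sample's segment form the region set. Each (region, sample) cell of
the resulting matrix then holds the log2 value of the sample's covering
segment, or the fill value (0 = log2-neutral, configurable) where the
sample has no segment — segment absence meaning no detected deviation
from diploid.

By construction a region is covered all-or-none by any given sample's
segments, so the matrix is exact: expanding every cell back to bases
reproduces the per-base value map implied by the raw segments.
Regions covered by no sample are not emitted (footprint-union
semantics); a whole-genome mode that also emits uncovered gaps is
available for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CnvSegment,
    CohortSample,
    GenomicInterval,
    ValidationError,
    karyotype_sort_key,
)

__all__ = ["RegionSet", "RegionMatrix", "build_regions", "fill_matrix", "project_segments"]


@dataclass
class RegionSet:
    """An ordered list of pairwise-disjoint regions, sorted by (chrom, start)."""

    regions: list[GenomicInterval]

    def __post_init__(self) -> None:
        ordered = sorted(
            self.regions,
            key=lambda r: (karyotype_sort_key(r.chromosome), r.start),
        )
        for prev, cur in zip(ordered, ordered[1:]):
            if prev.chromosome == cur.chromosome and cur.start <= prev.end:
                raise ValidationError(f"regions overlap: {prev} and {cur}")
        self.regions = ordered

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chromosome for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
            }
        )


@dataclass
class RegionMatrix:
    """Aligned region × sample copy-number values, with optional class labels."""

    region_set: RegionSet
    samples: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_set), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.region_set)} regions x {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            raise ValidationError("region matrix contains missing entries")
        if self.labels is not None:
            missing = [s for s in self.samples if s not in self.labels]
            if missing:
                raise ValidationError(f"samples without labels: {missing[:5]}")

    @property
    def n_regions(self) -> int:
        return len(self.region_set)

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValidationError("matrix carries no class labels")
        return np.array([self.labels[s] for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        frame = self.region_set.to_frame()
        for j, sample in enumerate(self.samples):
            frame[sample] = self.values[:, j]
        return frame

    def feature_matrix(self) -> np.ndarray:
        """Samples × regions array, the orientation model code expects."""
        return self.values.T.copy()


def build_regions(
    cohort: Sequence[CohortSample], emit_gaps: bool = False
) -> RegionSet:
    """Partition all samples' segment footprints into disjoint aligned regions.

    Per chromosome, breakpoints are the union of every segment's start
    and end+1 (closed-closed arithmetic with an end+1 sentinel avoids
    off-by-one at shared boundaries); regions are the intervals between
    consecutive breakpoints covered by at least one sample (all
    intervals, when ``emit_gaps``). Order of the cohort is irrelevant.
    """
    if not cohort:
        raise ValidationError("cannot build regions from an empty cohort")
    by_chrom: dict[str, list[CnvSegment]] = {}
    for sample in cohort:
        for seg in sample.segments:
            by_chrom.setdefault(seg.interval.chromosome, []).append(seg)
    regions: list[GenomicInterval] = []
    for chrom, segs in by_chrom.items():
        starts = np.array([s.interval.start for s in segs])
        ends = np.array([s.interval.end for s in segs])
        breaks = np.unique(np.concatenate([starts, ends + 1]))
        cand_start = breaks[:-1]
        cand_end = breaks[1:] - 1
        if emit_gaps:
            covered = np.ones(len(cand_start), dtype=bool)
        else:
            # a candidate is covered iff some segment spans it; candidates
            # never straddle a segment boundary, so testing the start suffices
            covered = np.zeros(len(cand_start), dtype=bool)
            for s, e in zip(starts, ends):
                covered |= (cand_start >= s) & (cand_start <= e)
        regions.extend(
            GenomicInterval(chrom, int(s), int(e))
            for s, e, c in zip(cand_start, cand_end, covered)
            if c
        )
    return RegionSet(regions)


def _segment_lookup(
    segments: Sequence[CnvSegment],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    table: dict[str, list[CnvSegment]] = {}
    for seg in segments:
        table.setdefault(seg.interval.chromosome, []).append(seg)
    out = {}
    for chrom, segs in table.items():
        segs = sorted(segs, key=lambda s: s.interval.start)
        out[chrom] = (
            np.array([s.interval.start for s in segs]),
            np.array([s.interval.end for s in segs]),
            np.array([s.value for s in segs]),
        )
    return out


def fill_matrix(
    cohort: Sequence[CohortSample],
    region_set: RegionSet,
    fill_value: float = 0.0,
) -> RegionMatrix:
    """Fill the region × sample matrix from each sample's covering segments.

    Requires the region set to refine every sample's segmentation (true
    for region sets from :func:`build_regions` on the same cohort); a
    segment partially overlapping a region is an internal-consistency
    error.
    """
    values = np.full((len(region_set), len(cohort)), fill_value, dtype=float)
    region_list = list(region_set)
    for j, sample in enumerate(cohort):
        lookup = _segment_lookup(sample.segments)
        for i, region in enumerate(region_list):
            entry = lookup.get(region.chromosome)
            if entry is None:
                continue
            starts, ends, vals = entry
            k = int(np.searchsorted(starts, region.start, side="right")) - 1
            if k < 0 or region.start > ends[k]:
                continue  # region starts outside every segment
            if region.end > ends[k]:
                raise ValidationError(
                    f"segment of sample {sample.sample_id!r} partially overlaps "
                    f"region {region}; region set does not refine this segmentation"
                )
            values[i, j] = vals[k]
    return RegionMatrix(
        region_set=region_set,
        samples=[s.sample_id for s in cohort],
        values=values,
    )


def project_segments(
    segments: Sequence[CnvSegment],
    region_set: RegionSet,
    fill_value: float = 0.0,
) -> np.ndarray:
    """Project one sample's segments onto an existing region set.

    Used to score new samples (e.g. a patient's lesions) against a
    region set built from a training cohort, whose breakpoints need not
    refine the new sample's segmentation. Each region value is the
    length-weighted mean of the log2 values over the region, counting
    uncovered bases as ``fill_value``; this reduces to the exact segment
    value whenever a single segment covers the whole region.
    """
    lookup = _segment_lookup(segments)
    out = np.full(len(region_set), float(fill_value))
    for i, region in enumerate(region_set):
        entry = lookup.get(region.chromosome)
        if entry is None:
            continue
        starts, ends, vals = entry
        lo = np.maximum(starts, region.start)
        hi = np.minimum(ends, region.end)
        overlap = np.clip(hi - lo + 1, 0, None)
        covered = int(overlap.sum())
        if covered == 0:
            continue
        total = float((overlap * vals).sum()) + fill_value * (region.length - covered)
        out[i] = total / region.length
    return out
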