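"""Domain types for somatic-event analysis of multifocal tumors.

All genomic coordinates are 1-based and inclusive at both ends, the
convention of segmented copy-number (SEG) tables and of printed clinical
reports. Converters to/from 0-based half-open coordinates live at the
I/O boundary only (:mod:`clonorigin.io`).

Chromosome labels are normalized to carry a ``chr`` prefix and compared
as exact strings; no ordering is assumed beyond the configurable
karyotype order used when sorting output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ValidationError",
    "GenomicInterval",
    "MutationCall",
    "GeneCnvEvent",
    "CnvSegment",
    "LesionProfile",
    "CohortSample",
    "normalize_chromosome",
    "karyotype_sort_key",
    "check_segments_disjoint",
]


class ValidationError(ValueError):
    """An input record violates a domain invariant.

    Raised at parse/construction time; invalid records are rejected,
    never silently repaired.
    """


#: Default karyotype order for output sorting (chr1..chr22, chrX, chrY, chrM).
DEFAULT_KARYOTYPE: tuple[str, ...] = tuple(
    f"chr{c}" for c in [*map(str, range(1, 23)), "X", "Y", "M"]
)


def normalize_chromosome(label: str) -> str:
    """Return *label* with a ``chr`` prefix, stripping surrounding space.

    ``"4"`` and ``"chr4"`` normalize identically; an empty label is an
    error.
    """
    label = str(label).strip()
    if not label:
        raise ValidationError("chromosome label must be non-empty")
    if not label.startswith("chr"):
        label = "chr" + label
    return label


def karyotype_sort_key(chrom: str, order: Sequence[str] = DEFAULT_KARYOTYPE):
    """Sort key placing known chromosomes in karyotype order, others after."""
    try:
        return (0, order.index(chrom), chrom)
    except ValueError:
        return (1, 0, chrom)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span with 1-based inclusive endpoints."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 1:
            raise ValidationError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"interval end {self.end} precedes start {self.start}"
            )

    @property
    def length(self) -> int:
        """Number of bases covered (inclusive of both endpoints)."""
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chromosome}:{self.start:,}-{self.end:,}"


@dataclass(frozen=True)
class MutationCall:
    """One somatic substitution or small indel in one sample.

    ``region_class`` distinguishes exonic from non-exonic calls;
    ``in_dbsnp`` / ``in_germline`` are provenance flags supplied by the
    upstream caller (matched-normal comparison and dbSNP lookup happen
    upstream; here they are plain input columns).
    """

    sample: str
    gene: str
    chromosome: str
    position: int
    ref: str
    alt: str
    region_class: str = "exon"
    allele_frequency: float = 0.0
    coverage: int = 0
    alt_reads: int = 0
    in_dbsnp: bool = False
    in_germline: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        object.__setattr__(self, "position", int(self.position))
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValidationError(
                f"allele_frequency {self.allele_frequency} outside [0, 1] "
                f"({self.sample} {self.gene})"
            )
        if self.coverage < 0 or self.alt_reads < 0:
            raise ValidationError("coverage and alt_reads must be non-negative")
        if self.alt_reads > self.coverage:
            raise ValidationError(
                f"alt_reads {self.alt_reads} exceeds coverage {self.coverage} "
                f"({self.sample} {self.gene})"
            )
        if self.region_class not in ("exon", "non-exon"):
            raise ValidationError(
                f"region_class must be 'exon' or 'non-exon', got {self.region_class!r}"
            )

    def identity_key(self, strict: bool = True) -> tuple:
        """Matching key used when deciding whether two calls are shared.

        Strict mode includes the ref/alt alleles; the relaxed mode
        matches on gene plus genomic coordinate only.
        """
        key = (self.gene, self.chromosome, self.position)
        if strict:
            key = key + (self.ref, self.alt)
        return key


@dataclass(frozen=True)
class GeneCnvEvent:
    """A gene-level copy-number call (gain or loss) with its log2 ratio."""

    sample: str
    gene: str
    direction: str
    log2_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValidationError(
                f"direction must be 'gain' or 'loss', got {self.direction!r}"
            )

    def identity_key(self) -> tuple:
        return (self.gene, self.direction)


@dataclass(frozen=True)
class CnvSegment:
    """A per-sample segmented copy-number value on the log2 scale (0 = neutral)."""

    sample: str
    interval: GenomicInterval
    value: float


def check_segments_disjoint(segments: Iterable[CnvSegment]) -> None:
    """Raise :class:`ValidationError` if segments of one sample overlap.

    Segments are grouped by (sample, chromosome); any overlapping pair
    within a group is named in the error.
    """
    by_key: dict[tuple[str, str], list[CnvSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample, seg.interval.chromosome), []).append(seg)
    for (sample, _chrom), group in by_key.items():
        group = sorted(group, key=lambda s: (s.interval.start, s.interval.end))
        for prev, cur in zip(group, group[1:]):
            if cur.interval.start <= prev.interval.end:
                raise ValidationError(
                    f"overlapping segments in sample {sample!r}: "
                    f"{prev.interval} and {cur.interval}"
                )


@dataclass
class LesionProfile:
    """The filtered somatic events of one tumor mass.

    ``cnv_intervals`` holds chromosome-level CNV events as
    (interval, direction) pairs; ``gene_cnvs`` holds gene-level calls.
    All member records must carry the lesion's own sample id.
    """

    lesion_id: str
    tissue_label: str = ""
    mutations: list[MutationCall] = field(default_factory=list)
    cnv_intervals: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    gene_cnvs: list[GeneCnvEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.mutations:
            if m.sample != self.lesion_id:
                raise ValidationError(
                    f"mutation sample {m.sample!r} does not match lesion "
                    f"{self.lesion_id!r}"
                )
        for g in self.gene_cnvs:
            if g.sample != self.lesion_id:
                raise ValidationError(
                    f"gene CNV sample {g.sample!r} does not match lesion "
                    f"{self.lesion_id!r}"
                )

    @property
    def event_burden(self) -> int:
        """Total somatic events: mutations + interval CNVs + gene CNVs."""
        return len(self.mutations) + len(self.cnv_intervals) + len(self.gene_cnvs)


@dataclass
class CohortSample:
    """One labelled sample of a training cohort: segmented CNV profile + class."""

    sample_id: str
    cancer_type: str
    segments: list[CnvSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for seg in self.segments:
            if seg.sample != self.sample_id:
                raise ValidationError(
                    f"segment sample {seg.sample!r} does not match "
                    f"{self.sample_id!r}"
                )
        check_segments_disjoint(self.segments)
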