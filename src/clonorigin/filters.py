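"""Inclusion rules for candidate somatic calls and gene-level CNV thresholding.

The mutation filter implements the standard deep-targeted-panel rules:
a call is retained only when it is supported by at least ``min_coverage``
total reads and at least ``min_alt_reads`` variant-supporting reads, and
is neither a catalogued dbSNP polymorphism nor present in the patient's
matched germline sample. The thresholds are read literally: a call at
exactly 100x with exactly five supporting reads is retained.

Gene CNV calls use a symmetric log2 read-depth-ratio threshold with
strict inequalities: gain above +t, loss below -t, neutral otherwise
(t = 0.7 by default).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field

from .core import GeneCnvEvent, MutationCall, ValidationError

__all__ = [
    "FilterPolicy",
    "filter_mutations",
    "call_gene_cnv",
    "low_af_fraction",
    "summarize_lesion",
    "LesionSummary",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds and switches governing somatic-event inclusion.

    Parameters
    ----------
    min_coverage : int
        Minimum total read depth for a mutation call (default 100).
    min_alt_reads : int
        Minimum variant-supporting reads (default 5). ``alt_read_mode``
        selects whether this counts variant-supporting reads
        (``"alt"``, default) or total reads at the locus (``"total"``).
    exclude_dbsnp, exclude_germline : bool
        Drop calls catalogued in dbSNP / present in matched germline.
    low_af_cutoff : float
        Strict upper bound defining a "low allele frequency" call
        (default 0.05), used only for descriptive summaries.
    cnv_log2_threshold : float
        Magnitude of the gene-CNV log2 read-depth-ratio threshold
        (default 0.7).
    coverage_sd_mode : str
        ``"sample"`` (n-1 divisor, default) or ``"population"`` for the
        coverage standard deviation in lesion summaries.
    """

    min_coverage: int = 100
    min_alt_reads: int = 5
    exclude_dbsnp: bool = True
    exclude_germline: bool = True
    low_af_cutoff: float = 0.05
    cnv_log2_threshold: float = 0.7
    alt_read_mode: str = "alt"
    coverage_sd_mode: str = "sample"

    def __post_init__(self) -> None:
        if self.min_coverage < 0 or self.min_alt_reads < 0:
            raise ValidationError("filter thresholds must be non-negative")
        if not 0.0 < self.low_af_cutoff < 1.0:
            raise ValidationError("low_af_cutoff must lie in (0, 1)")
        if self.cnv_log2_threshold < 0:
            raise ValidationError("cnv_log2_threshold must be non-negative")
        if self.alt_read_mode not in ("alt", "total"):
            raise ValidationError("alt_read_mode must be 'alt' or 'total'")
        if self.coverage_sd_mode not in ("sample", "population"):
            raise ValidationError("coverage_sd_mode must be 'sample' or 'population'")


def _passes(call: MutationCall, policy: FilterPolicy) -> bool:
    if call.coverage < policy.min_coverage:
        return False
    support = call.alt_reads if policy.alt_read_mode == "alt" else call.coverage
    if support < policy.min_alt_reads:
        return False
    if policy.exclude_dbsnp and call.in_dbsnp:
        return False
    if policy.exclude_germline and call.in_germline:
        return False
    return True


def filter_mutations(
    candidates: list[MutationCall], policy: FilterPolicy | None = None
) -> list[MutationCall]:
    """Return the candidates passing every inclusion rule, order preserved.

    The filter is evaluated per candidate independently (no rescue of
    low-support calls shared across lesions) and is idempotent.
    """
    policy = policy or FilterPolicy()
    return [c for c in candidates if _passes(c, policy)]


def call_gene_cnv(
    gene: str, log2_ratio: float, policy: FilterPolicy | None = None
) -> str:
    """Classify a gene's log2 read-depth ratio as ``gain``/``loss``/``neutral``.

    Strict inequalities on both sides; values at exactly +-threshold are
    neutral. Non-finite input is rejected.
    """
    policy = policy or FilterPolicy()
    if not math.isfinite(log2_ratio):
        raise ValidationError(f"non-finite log2 ratio for gene {gene!r}")
    t = policy.cnv_log2_threshold
    if log2_ratio > t:
        return "gain"
    if log2_ratio < -t:
        return "loss"
    return "neutral"


def gene_cnv_events(
    sample: str, gene_log2: dict[str, float], policy: FilterPolicy | None = None
) -> list[GeneCnvEvent]:
    """Threshold a {gene: log2 ratio} map into gain/loss events (neutral dropped)."""
    policy = policy or FilterPolicy()
    events = []
    for gene, log2 in gene_log2.items():
        direction = call_gene_cnv(gene, log2, policy)
        if direction != "neutral":
            events.append(
                GeneCnvEvent(
                    sample=sample, gene=gene, direction=direction, log2_ratio=log2
                )
            )
    return events


def low_af_fraction(
    mutations: list[MutationCall], policy: FilterPolicy | None = None
) -> float:
    """Fraction of calls with allele frequency strictly below the cutoff."""
    policy = policy or FilterPolicy()
    if not mutations:
        raise ValidationError("low_af_fraction is undefined for an empty list")
    n_low = sum(1 for m in mutations if m.allele_frequency < policy.low_af_cutoff)
    return n_low / len(mutations)


@dataclass(frozen=True)
class LesionSummary:
    """Descriptive per-lesion statistics over filtered events."""

    n_mutations: int
    n_exon_mutations: int
    n_genes: int
    n_gene_cnvs: int
    coverage_mean: float
    coverage_sd: float
    af_range: dict[str, tuple[float, float]] = field(default_factory=dict)


def summarize_lesion(
    mutations: list[MutationCall],
    gene_cnvs: list[GeneCnvEvent] | None = None,
    policy: FilterPolicy | None = None,
) -> LesionSummary:
    """Summarize one lesion's filtered events.

    Coverage sd uses the n-1 (sample) divisor by default; a single
    mutation reports sd 0 by convention. AF min-max is reported per
    region class (exon / non-exon).
    """
    policy = policy or FilterPolicy()
    gene_cnvs = gene_cnvs or []
    coverages = [m.coverage for m in mutations]
    if len(coverages) >= 2:
        sd = (
            statistics.stdev(coverages)
            if policy.coverage_sd_mode == "sample"
            else statistics.pstdev(coverages)
        )
    else:
        sd = 0.0
    af_range: dict[str, tuple[float, float]] = {}
    for region_class in ("exon", "non-exon"):
        afs = [m.allele_frequency for m in mutations if m.region_class == region_class]
        if afs:
            af_range[region_class] = (min(afs), max(afs))
    return LesionSummary(
        n_mutations=len(mutations),
        n_exon_mutations=sum(1 for m in mutations if m.region_class == "exon"),
        n_genes=len({m.gene for m in mutations}),
        n_gene_cnvs=len(gene_cnvs),
        coverage_mean=statistics.fmean(coverages) if coverages else 0.0,
        coverage_sd=sd,
        af_range=af_range,
    )
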