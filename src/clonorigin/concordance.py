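"""Shared-event concordance between tumor lesions and relatedness inference.

Under single-clonal evolution, lesions descending from one ancestral
cell population carry a common truncal set of somatic events; lesions
that diverged later share additional lineage events. Counting shared
mutations, identical-interval CNVs and shared gene-level CNV calls
between every pair of lesions therefore both tests clonal relatedness
and orders the lesions: the pair sharing the most events diverged last,
and the lesion with the fewest total acquired events is the best
candidate for the origin (metastases accumulate alterations on top of
the founder genome).

Matching rules
--------------
* Mutations are shared when gene and genomic coordinate match; strict
  mode (default) additionally requires identical ref/alt alleles, since
  coordinate-only matching can merge distinct substitutions.
* Chromosome-level CNVs are shared only when their intervals are
  *exactly* equal (chromosome, start and end); an optional
  reciprocal-overlap mode exists but is off by default.
* Gene CNVs are shared when gene and direction (gain/loss) match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .core import GenomicInterval, LesionProfile, ValidationError

__all__ = [
    "SharedEventReport",
    "RelatednessOrdering",
    "shared_mutations",
    "shared_cnv_intervals",
    "shared_gene_cnvs",
    "venn_counts",
    "union_from_counts",
    "relatedness_score",
    "event_burden",
    "infer_route",
]


def shared_mutations(
    a: LesionProfile, b: LesionProfile, strict: bool = True
) -> set[tuple]:
    """Keys of mutations present in both lesions.

    A mutation is shared iff gene and (chromosome, position) match; with
    ``strict`` (default) ref/alt must also match.
    """
    keys_a = {m.identity_key(strict) for m in a.mutations}
    keys_b = {m.identity_key(strict) for m in b.mutations}
    return keys_a & keys_b


def _interval_overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chromosome != b.chromosome:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def shared_cnv_intervals(
    a: LesionProfile,
    b: LesionProfile,
    match_direction: bool = True,
    reciprocal_overlap: float | None = None,
) -> set[GenomicInterval]:
    """Chromosome-level CNV intervals present in both lesions.

    Default matching is exact interval identity (chromosome, start, end
    all equal). Passing ``reciprocal_overlap`` (a fraction in (0, 1])
    instead matches intervals whose mutual overlap covers at least that
    fraction of *both* intervals; the matched interval reported is the
    one from lesion ``a``.
    """
    if reciprocal_overlap is None:
        set_a = {(iv, d) if match_direction else iv for iv, d in a.cnv_intervals}
        set_b = {(iv, d) if match_direction else iv for iv, d in b.cnv_intervals}
        common = set_a & set_b
        return {item[0] if match_direction else item for item in common}
    if not 0.0 < reciprocal_overlap <= 1.0:
        raise ValidationError("reciprocal_overlap must lie in (0, 1]")
    matched = set()
    for iv_a, d_a in a.cnv_intervals:
        for iv_b, d_b in b.cnv_intervals:
            if match_direction and d_a != d_b:
                continue
            ov = _interval_overlap_len(iv_a, iv_b)
            if (
                ov >= reciprocal_overlap * iv_a.length
                and ov >= reciprocal_overlap * iv_b.length
            ):
                matched.add(iv_a)
    return matched


def shared_gene_cnvs(*lesions: LesionProfile) -> set[tuple]:
    """(gene, direction) pairs present in every given lesion."""
    if not lesions:
        return set()
    sets = [{g.identity_key() for g in lesion.gene_cnvs} for lesion in lesions]
    return set.intersection(*sets)


@dataclass
class SharedEventReport:
    """Venn decomposition of shared somatic events across lesions."""

    lesion_ids: list[str]
    per_lesion_mutations: dict[str, int]
    pairwise_shared_mutations: dict[tuple[str, str], int]
    triple_shared_mutations: int
    union_size: int
    pairwise_shared_cnvs: dict[tuple[str, str], int] = field(default_factory=dict)
    pairwise_shared_gene_cnvs: dict[tuple[str, str], int] = field(default_factory=dict)
    triple_shared_gene_cnvs: int = 0

    def to_dict(self) -> dict:
        return {
            "lesion_ids": self.lesion_ids,
            "per_lesion_mutations": self.per_lesion_mutations,
            "pairwise_shared_mutations": {
                "|".join(k): v for k, v in self.pairwise_shared_mutations.items()
            },
            "triple_shared_mutations": self.triple_shared_mutations,
            "union_size": self.union_size,
            "pairwise_shared_cnvs": {
                "|".join(k): v for k, v in self.pairwise_shared_cnvs.items()
            },
            "pairwise_shared_gene_cnvs": {
                "|".join(k): v for k, v in self.pairwise_shared_gene_cnvs.items()
            },
            "triple_shared_gene_cnvs": self.triple_shared_gene_cnvs,
        }


def union_from_counts(
    singles: list[int], pairwise: list[int], triple: int
) -> int:
    """Union size of three sets by inclusion-exclusion from tabulated counts.

    ``|A u B u C| = sum singles - sum pairwise + triple``. Used when only
    the published Venn counts are available rather than the event lists.
    """
    if len(singles) != 3 or len(pairwise) != 3:
        raise ValidationError("expected three per-set and three pairwise counts")
    return sum(singles) - sum(pairwise) + triple


def venn_counts(lesions: list[LesionProfile], strict: bool = True) -> SharedEventReport:
    """Full Venn decomposition of mutations (and CNV sharing) for >= 3 lesions.

    Counts are computed by explicit set algebra on mutation identity
    keys, so the inclusion-exclusion identity holds exactly by
    construction. ``triple_shared_mutations`` is the intersection of all
    lesions (for k > 3, the all-way intersection).
    """
    ids = [l.lesion_id for l in lesions]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate lesion ids in {ids}")
    if len(lesions) < 2:
        raise ValidationError("need at least two lesions")
    key_sets = {
        l.lesion_id: {m.identity_key(strict) for m in l.mutations} for l in lesions
    }
    pairwise_mut = {}
    pairwise_cnv = {}
    pairwise_gene = {}
    for a, b in combinations(lesions, 2):
        pair = (a.lesion_id, b.lesion_id)
        pairwise_mut[pair] = len(key_sets[a.lesion_id] & key_sets[b.lesion_id])
        pairwise_cnv[pair] = len(shared_cnv_intervals(a, b))
        pairwise_gene[pair] = len(shared_gene_cnvs(a, b))
    all_way = set.intersection(*key_sets.values())
    union = set.union(*key_sets.values())
    return SharedEventReport(
        lesion_ids=ids,
        per_lesion_mutations={i: len(key_sets[i]) for i in ids},
        pairwise_shared_mutations=pairwise_mut,
        triple_shared_mutations=len(all_way),
        union_size=len(union),
        pairwise_shared_cnvs=pairwise_cnv,
        pairwise_shared_gene_cnvs=pairwise_gene,
        triple_shared_gene_cnvs=len(shared_gene_cnvs(*lesions)),
    )


def relatedness_score(
    a: LesionProfile,
    b: LesionProfile,
    strict: bool = True,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Unweighted (by default) count of shared events between two lesions.

    score = #shared mutations + #shared CNV intervals + #shared gene
    CNVs; symmetric, and ``score(a, a)`` equals a's total event count.
    """
    w_mut, w_cnv, w_gene = weights
    return (
        w_mut * len(shared_mutations(a, b, strict))
        + w_cnv * len(shared_cnv_intervals(a, b))
        + w_gene * len(shared_gene_cnvs(a, b))
    )


def event_burden(lesion: LesionProfile) -> int:
    """Total acquired events of a lesion (mutations + CNVs + gene CNVs)."""
    return lesion.event_burden


@dataclass
class RelatednessOrdering:
    """Inferred relatedness structure of a multi-lesion patient."""

    closest_pair: tuple[str, str]
    burden_ranking: list[str]
    inferred_route: list[str]
    tie_flag: bool = False
    unresolved: bool = False

    def to_dict(self) -> dict:
        return {
            "closest_pair": list(self.closest_pair),
            "burden_ranking": self.burden_ranking,
            "inferred_route": self.inferred_route,
            "tie_flag": self.tie_flag,
            "unresolved": self.unresolved,
        }


def infer_route(lesions: list[LesionProfile], strict: bool = True) -> RelatednessOrdering:
    """Infer origin and metastatic route from burdens and pairwise scores.

    The origin is the lesion with the minimal total event burden (the
    ancestral population has acquired the fewest alterations); the route
    then chains the remaining lesions by descending relatedness to the
    current chain tail. Ties are broken lexicographically by lesion id
    and flagged. If every pairwise score is zero the ordering is
    returned flagged ``unresolved``.
    """
    if len(lesions) < 2:
        raise ValidationError("need at least two lesions to infer a route")
    by_id = {l.lesion_id: l for l in lesions}
    if len(by_id) != len(lesions):
        raise ValidationError("duplicate lesion ids")
    scores = {
        frozenset((a.lesion_id, b.lesion_id)): relatedness_score(a, b, strict)
        for a, b in combinations(lesions, 2)
    }
    burdens = {l.lesion_id: event_burden(l) for l in lesions}
    burden_ranking = sorted(by_id, key=lambda i: (burdens[i], i))

    best = max(scores.values())
    best_pairs = sorted(tuple(sorted(p)) for p, s in scores.items() if s == best)
    closest_pair = best_pairs[0]
    tie = len(best_pairs) > 1

    origin_burden = min(burdens.values())
    origin_candidates = sorted(i for i, b in burdens.items() if b == origin_burden)
    origin = origin_candidates[0]
    tie = tie or len(origin_candidates) > 1

    route = [origin]
    remaining = set(by_id) - {origin}
    while remaining:
        tail = route[-1]
        ranked = sorted(
            remaining, key=lambda i: (-scores[frozenset((tail, i))], i)
        )
        if len(ranked) > 1:
            top = scores[frozenset((tail, ranked[0]))]
            if scores[frozenset((tail, ranked[1]))] == top:
                tie = True
        route.append(ranked[0])
        remaining.discard(ranked[0])

    return RelatednessOrdering(
        closest_pair=closest_pair,
        burden_ranking=burden_ranking,
        inferred_route=route,
        tie_flag=tie,
        unresolved=(best == 0),
    )
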