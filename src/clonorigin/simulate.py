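"""Synthetic labelled CNV cohorts and clonal multi-lesion patients.

Two generators with fully recorded ground truth:

* :func:`generate_cohort` emulates a labelled multi-cancer training
  cohort of segmented copy-number profiles. Each cancer type is planted
  a disjoint set of signature regions where its samples carry a
  consistent log2 shift (default magnitude 0.8, Gaussian noise sd 0.1);
  on top, every sample receives passenger segments placed uniformly
  over the genome, mostly near-neutral with a small probability of a
  large sporadic shift. The defaults give three classes named after the
  hepatobiliary/pancreatic cancer types the pipeline targets.

* :func:`generate_patient` emulates one patient with synchronous
  multifocal lesions evolving clonally: all lesions inherit a truncal
  set of somatic mutations and the origin class's signature CNV profile;
  lesions on a lineage branch share additional events; each lesion then
  acquires private events. Per-lesion allele frequencies are drawn from
  Beta(1.2, 25), putting roughly two thirds of calls below AF 0.05 as is
  typical of deep-sequenced impure tumor samples. Event coordinates are globally
  unique, so shared-event counts computed downstream equal the
  generator's bookkeeping exactly.

Both generators are deterministic given their seed; per-sample child
seeds are derived from one ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    CnvSegment,
    CohortSample,
    GeneCnvEvent,
    GenomicInterval,
    LesionProfile,
    MutationCall,
    ValidationError,
)

__all__ = [
    "CohortSpec",
    "PatientSpec",
    "LineageBranch",
    "CohortTruth",
    "PatientTruth",
    "PatientCase",
    "generate_cohort",
    "generate_patient",
]

DEFAULT_GENOME: dict[str, int] = {
    "chr1": 50_000_000,
    "chr2": 50_000_000,
    "chr3": 50_000_000,
    "chr4": 50_000_000,
}

DEFAULT_CLASSES = (
    "cholangiocarcinoma",
    "hepatocellular_carcinoma",
    "pancreatic_carcinoma",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic labelled cohort."""

    class_names: tuple[str, ...] = DEFAULT_CLASSES
    samples_per_class: int = 40
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    n_signature_regions_per_class: int = 10
    signature_effect: float = 0.8
    signature_length_range: tuple[int, int] = (500_000, 2_000_000)
    n_passenger_segments: int = 10
    passenger_length_range: tuple[int, int] = (200_000, 2_000_000)
    passenger_inflate_prob: float = 0.05
    segment_value_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_class < 0 or self.n_signature_regions_per_class < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_passenger_segments < 0:
            raise ValidationError("counts must be non-negative")
        if not np.isfinite(self.signature_effect) or not np.isfinite(
            self.segment_value_noise_sd
        ):
            raise ValidationError("effect and noise must be finite")
        if len(self.class_names) < 1:
            raise ValidationError("need at least one class")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort."""

    planted: dict[str, list[tuple[GenomicInterval, int]]]  # class -> (region, sign)
    labels: dict[str, str]  # sample -> class

    def planted_regions(self, cls: str) -> list[GenomicInterval]:
        return [iv for iv, _ in self.planted[cls]]


def _overlaps_any(iv: GenomicInterval, occupied: list[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in occupied)


def _place_interval(
    rng: np.random.Generator,
    genome: dict[str, int],
    occupied: list[GenomicInterval],
    length_range: tuple[int, int],
    max_tries: int = 2000,
) -> GenomicInterval:
    chroms = list(genome)
    sizes = np.array([genome[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    for _ in range(max_tries):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if length > genome[chrom]:
            raise ValidationError(
                f"requested interval length {length} exceeds {chrom} size"
            )
        start = int(rng.integers(1, genome[chrom] - length + 2))
        iv = GenomicInterval(chrom, start, start + length - 1)
        if not _overlaps_any(iv, occupied):
            return iv
    raise ValidationError("could not place a disjoint interval; genome too crowded")


def generate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[list[CohortSample], CohortTruth]:
    """Generate a labelled cohort of segmented CNV profiles plus its truth."""
    spec = spec or CohortSpec()
    root = np.random.SeedSequence(spec.seed)
    plant_rng = np.random.default_rng(root.spawn(1)[0])

    planted: dict[str, list[tuple[GenomicInterval, int]]] = {}
    occupied: list[GenomicInterval] = []
    for cls in spec.class_names:
        regions = []
        for _ in range(spec.n_signature_regions_per_class):
            iv = _place_interval(
                plant_rng, spec.genome, occupied, spec.signature_length_range
            )
            occupied.append(iv)
            sign = int(plant_rng.choice([-1, 1]))
            regions.append((iv, sign))
        planted[cls] = regions

    samples: list[CohortSample] = []
    labels: dict[str, str] = {}
    child_seeds = root.spawn(len(spec.class_names) * spec.samples_per_class + 1)[1:]
    idx = 0
    for cls in spec.class_names:
        for i in range(spec.samples_per_class):
            rng = np.random.default_rng(child_seeds[idx])
            idx += 1
            sample_id = f"{cls}_{i:03d}"
            segs: list[CnvSegment] = []
            own: list[GenomicInterval] = []
            for iv, sign in planted[cls]:
                value = sign * spec.signature_effect + rng.normal(
                    0.0, spec.segment_value_noise_sd
                )
                segs.append(CnvSegment(sample_id, iv, float(value)))
                own.append(iv)
            for _ in range(spec.n_passenger_segments):
                iv = _place_interval(
                    rng, spec.genome, own, spec.passenger_length_range
                )
                own.append(iv)
                value = rng.normal(0.0, spec.segment_value_noise_sd)
                if rng.random() < spec.passenger_inflate_prob:
                    value += float(rng.choice([-1, 1])) * spec.signature_effect
                segs.append(CnvSegment(sample_id, iv, float(value)))
            samples.append(CohortSample(sample_id, cls, segs))
            labels[sample_id] = cls
    return samples, CohortTruth(planted=planted, labels=labels)


@dataclass(frozen=True)
class LineageBranch:
    """Events shared by a proper subset of lesions (acquired after divergence)."""

    lesions: tuple[str, ...]
    n_mutations: int = 0
    n_cnvs: int = 0
    gene_cnvs: tuple[tuple[str, str], ...] = ()


#: Gene-level truncal CNV events of the default patient (gene, direction).
DEFAULT_TRUNCAL_GENE_CNVS = (
    ("MDM2", "gain"),
    ("VHL", "loss"),
    ("PLA2G1B", "loss"),
    ("LIMK1", "loss"),
    ("KEAP1", "loss"),
)


@dataclass(frozen=True)
class PatientSpec:
    """Parameters of the synthetic clonal multi-lesion patient.

    The default emulates a three-lesion case: a pancreatic origin lesion
    and a two-lesion branch (bile duct, omentum) that diverged later and
    therefore shares extra events; private event counts increase along
    the route, so burdens order the lesions origin-first.
    """

    lesion_ids: tuple[str, ...] = ("pancreas", "bile_duct", "omentum")
    origin_class: str = "pancreatic_carcinoma"
    n_truncal_mutations: int = 29
    truncal_gene_cnvs: tuple[tuple[str, str], ...] = DEFAULT_TRUNCAL_GENE_CNVS
    branches: tuple[LineageBranch, ...] = (
        LineageBranch(
            lesions=("bile_duct", "omentum"),
            n_mutations=17,
            n_cnvs=6,
            gene_cnvs=(("CDK4", "gain"), ("GLI1", "gain")),
        ),
    )
    n_private_mutations: tuple[int, ...] = (25, 38, 42)
    n_private_cnvs: tuple[int, ...] = (1, 2, 3)
    cnv_length_range: tuple[int, int] = (100_000, 3_000_000)
    af_beta_params: tuple[float, float] = (1.2, 25.0)
    coverage_mean: float = 450.0
    coverage_sd: float = 200.0
    exon_fraction: float = 0.45
    segment_value_noise_sd: float = 0.1
    signature_effect: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lesion_ids) < 2:
            raise ValidationError("a patient needs at least two lesions")
        if len(set(self.lesion_ids)) != len(self.lesion_ids):
            raise ValidationError("duplicate lesion ids")
        if len(self.n_private_mutations) != len(self.lesion_ids) or len(
            self.n_private_cnvs
        ) != len(self.lesion_ids):
            raise ValidationError("private event counts must match lesion count")
        for branch in self.branches:
            unknown = set(branch.lesions) - set(self.lesion_ids)
            if unknown:
                raise ValidationError(f"branch names unknown lesions {unknown}")
            if not 0 < len(branch.lesions) < len(self.lesion_ids):
                raise ValidationError(
                    "a lineage branch must cover a proper non-empty lesion subset"
                )


@dataclass
class PatientTruth:
    """Generator bookkeeping sufficient to score downstream inference."""

    origin_lesion: str
    origin_class: str
    route: list[str]
    pairwise_shared_mutations: dict[tuple[str, str], int]
    pairwise_shared_cnvs: dict[tuple[str, str], int]
    all_shared_mutations: int
    mutation_union: int
    per_lesion_mutations: dict[str, int]


@dataclass
class PatientCase:
    lesions: list[LesionProfile]
    truth: PatientTruth


def _draw_mutation_site(
    rng: np.random.Generator,
    genome: dict[str, int],
    used: set[tuple[str, int]],
    gene_counter: list[int],
) -> tuple[str, str, int, str, str]:
    chroms = list(genome)
    while True:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, genome[chrom] + 1))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            break
    gene_counter[0] += 1
    gene = f"GENE{gene_counter[0]:04d}"
    ref, alt = rng.choice(4, size=2, replace=False)
    return gene, chrom, pos, str(_BASES[ref]), str(_BASES[alt])


def generate_patient(
    spec: PatientSpec | None = None,
    cohort_truth: CohortTruth | None = None,
    genome: dict[str, int] | None = None,
) -> PatientCase:
    """Generate a clonal multi-lesion patient with recorded truth.

    If ``cohort_truth`` is given, the truncal copy-number profile is the
    origin class's planted signature regions (with the planted effect
    signs), so lesions classify into the origin class under a model
    trained on the matching cohort; otherwise truncal CNVs are placed
    uniformly like every other event.
    """
    spec = spec or PatientSpec()
    genome = dict(genome or DEFAULT_GENOME)
    if cohort_truth is not None and spec.origin_class not in cohort_truth.planted:
        raise ValidationError(
            f"origin class {spec.origin_class!r} absent from cohort truth"
        )
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    used_sites: set[tuple[str, int]] = set()
    gene_counter = [0]

    def new_mutation_events(n: int) -> list[tuple]:
        return [
            _draw_mutation_site(rng, genome, used_sites, gene_counter)
            for _ in range(n)
        ]

    # truncal copy-number profile
    occupied: list[GenomicInterval] = []
    truncal_cnvs: list[tuple[GenomicInterval, int]] = []
    if cohort_truth is not None:
        for iv, sign in cohort_truth.planted[spec.origin_class]:
            truncal_cnvs.append((iv, sign))
            occupied.append(iv)
        # keep every other class's signature regions neutral in the patient
        for cls, regions in cohort_truth.planted.items():
            if cls != spec.origin_class:
                occupied.extend(iv for iv, _ in regions)

    truncal_mutations = new_mutation_events(spec.n_truncal_mutations)
    branch_events = []
    for branch in spec.branches:
        muts = new_mutation_events(branch.n_mutations)
        cnvs = []
        for _ in range(branch.n_cnvs):
            iv = _place_interval(rng, genome, occupied, spec.cnv_length_range)
            occupied.append(iv)
            cnvs.append((iv, int(rng.choice([-1, 1]))))
        branch_events.append((branch, muts, cnvs))
    private_events = []
    for lesion_id, n_mut, n_cnv in zip(
        spec.lesion_ids, spec.n_private_mutations, spec.n_private_cnvs
    ):
        muts = new_mutation_events(n_mut)
        cnvs = []
        for _ in range(n_cnv):
            iv = _place_interval(rng, genome, occupied, spec.cnv_length_range)
            occupied.append(iv)
            cnvs.append((iv, int(rng.choice([-1, 1]))))
        private_events.append((lesion_id, muts, cnvs))

    a, b = spec.af_beta_params
    lesions: list[LesionProfile] = []
    for li, lesion_id in enumerate(spec.lesion_ids):
        mut_events = list(truncal_mutations)
        cnv_events = list(truncal_cnvs)
        gene_events: list[tuple[str, str]] = list(spec.truncal_gene_cnvs)
        for branch, muts, cnvs in branch_events:
            if lesion_id in branch.lesions:
                mut_events += muts
                cnv_events += cnvs
                gene_events += list(branch.gene_cnvs)
        mut_events += private_events[li][1]
        cnv_events += private_events[li][2]

        calls = []
        for gene, chrom, pos, ref, alt in mut_events:
            af = float(rng.beta(a, b))
            coverage = max(100, int(round(rng.normal(spec.coverage_mean,
                                                     spec.coverage_sd))))
            alt_reads = min(coverage, max(5, int(round(af * coverage))))
            calls.append(
                MutationCall(
                    sample=lesion_id,
                    gene=gene,
                    chromosome=chrom,
                    position=pos,
                    ref=ref,
                    alt=alt,
                    region_class="exon"
                    if rng.random() < spec.exon_fraction
                    else "non-exon",
                    allele_frequency=alt_reads / coverage,
                    coverage=coverage,
                    alt_reads=alt_reads,
                )
            )
        intervals = [
            (iv, "gain" if sign > 0 else "loss") for iv, sign in cnv_events
        ]
        gene_cnvs = [
            GeneCnvEvent(
                sample=lesion_id,
                gene=gene,
                direction=direction,
                log2_ratio=(1.0 if direction == "gain" else -1.0)
                * spec.signature_effect,
            )
            for gene, direction in gene_events
        ]
        lesions.append(
            LesionProfile(
                lesion_id=lesion_id,
                tissue_label=lesion_id,
                mutations=calls,
                cnv_intervals=intervals,
                gene_cnvs=gene_cnvs,
            )
        )

    # bookkeeping: shared = truncal + sum of branches containing both lesions
    per_lesion = {}
    for li, lesion_id in enumerate(spec.lesion_ids):
        n = spec.n_truncal_mutations + spec.n_private_mutations[li]
        for branch, *_ in branch_events:
            if lesion_id in branch.lesions:
                n += branch.n_mutations
        per_lesion[lesion_id] = n
    pair_mut = {}
    pair_cnv = {}
    for i, x in enumerate(spec.lesion_ids):
        for y in spec.lesion_ids[i + 1 :]:
            m = spec.n_truncal_mutations
            c = len(truncal_cnvs)
            for branch, *_ in branch_events:
                if x in branch.lesions and y in branch.lesions:
                    m += branch.n_mutations
                    c += branch.n_cnvs
            pair_mut[(x, y)] = m
            pair_cnv[(x, y)] = c
    union = (
        spec.n_truncal_mutations
        + sum(br.n_mutations for br in spec.branches)
        + sum(spec.n_private_mutations)
    )

    # the true route orders lesions by acquired-event burden from the origin
    burdens = {
        lid: per_lesion[lid]
        + len(lesions[i].cnv_intervals)
        + len(lesions[i].gene_cnvs)
        for i, lid in enumerate(spec.lesion_ids)
    }
    route = sorted(spec.lesion_ids, key=lambda l: (burdens[l], l))
    truth = PatientTruth(
        origin_lesion=route[0],
        origin_class=spec.origin_class,
        route=route,
        pairwise_shared_mutations=pair_mut,
        pairwise_shared_cnvs=pair_cnv,
        all_shared_mutations=spec.n_truncal_mutations,
        mutation_union=union,
        per_lesion_mutations=per_lesion,
    )
    return PatientCase(lesions=lesions, truth=truth)


def lesion_segments(lesion: LesionProfile, effect: float = 0.8,
                    noise_sd: float = 0.0,
                    rng: np.random.Generator | None = None) -> list[CnvSegment]:
    """Render a lesion's interval CNV events as copy-number segments.

    Gains map to +effect, losses to -effect, with optional Gaussian
    noise; used to project patient lesions onto a cohort region set.
    """
    rng = rng or np.random.default_rng(0)
    segs = []
    for iv, direction in lesion.cnv_intervals:
        value = (effect if direction == "gain" else -effect) + (
            rng.normal(0.0, noise_sd) if noise_sd else 0.0
        )
        segs.append(CnvSegment(lesion.lesion_id, iv, float(value)))
    return segs
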