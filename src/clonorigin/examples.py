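"""A worked three-lesion case for demonstrations and cross-checks.

The numbers come from a published clinical case of synchronous
multifocal tumors in the pancreatic tail, upper biliary duct and
omentum: the tabulated Venn counts of somatic mutations across the
three masses, the chromosome-level CNV intervals shared between lesion
pairs, and the gene-level CNV calls. Only the published summary values
are encoded; full per-call depth fields are not public, so the mutation
records carry representative synthetic depths (clearly above the
100x / 5-read inclusion thresholds).
"""

from __future__ import annotations

from .core import GeneCnvEvent, GenomicInterval, LesionProfile, MutationCall

__all__ = ["reported_venn_counts", "three_lesion_case", "TP53_EXAMPLE"]


def reported_venn_counts() -> dict:
    """Tabulated mutation Venn counts of the three-lesion case.

    Per-lesion totals, pairwise intersections and the triple
    intersection, as published; the union follows by
    inclusion-exclusion.
    """
    return {
        "per_lesion": {"pancreas": 63, "bile_duct": 84, "omentum": 88},
        "pairwise": {
            ("pancreas", "bile_duct"): 38,
            ("pancreas", "omentum"): 37,
            ("bile_duct", "omentum"): 46,
        },
        "triple": 29,
    }


#: The TP53 substitution found in all three lesions, with its per-lesion
#: allele frequencies (bile duct, omentum, pancreas).
TP53_EXAMPLE = {
    "gene": "TP53",
    "chromosome": "chr17",
    "position": 7577538,
    "ref": "C",
    "alt": "T",
    "region_class": "exon",
    "allele_frequency": {"bile_duct": 0.156, "omentum": 0.084, "pancreas": 0.06},
}

# Chromosome-level CNV intervals shared between lesion pairs. Directions
# are not part of the published summary; a uniform synthetic "gain" is
# used, which leaves identical-interval matching unaffected.
_BILE_OMENTUM_SHARED = [
    GenomicInterval("chr4", 143_211_964, 146_188_881),
    GenomicInterval("chr12", 57_810_254, 58_498_926),
    GenomicInterval("chr13", 48_964_265, 49_017_901),
    GenomicInterval("chr13", 86_031_023, 90_196_888),
    GenomicInterval("chr16", 30_095_734, 35_271_725),
    GenomicInterval("chrY", 2_660_163, 28_799_935),
]
_BILE_PANCREAS_SHARED = [GenomicInterval("chrX", 177_942, 2_686_899)]

# Private (unshared) intervals per lesion, synthetic placeholders that
# keep the pairwise intersections at exactly 6 / 1 / 0.
_PRIVATE = {
    "pancreas": [GenomicInterval("chr2", 10_000_000, 12_000_000)],
    "bile_duct": [GenomicInterval("chr3", 5_000_000, 9_000_000)],
    "omentum": [GenomicInterval("chr8", 20_000_000, 21_500_000)],
}

# Gene-level CNV calls: the five pancreas events are shared by all three
# lesions; the biliary duct and omentum additionally share CDK4 and GLI1
# gains.
_PANCREAS_GENE_CNVS = [
    ("MDM2", "gain"),
    ("VHL", "loss"),
    ("PLA2G1B", "loss"),
    ("LIMK1", "loss"),
    ("KEAP1", "loss"),
]
_EXTRA_BILE_OMENTUM = [("CDK4", "gain"), ("GLI1", "gain")]


def _tp53(sample: str) -> MutationCall:
    af = TP53_EXAMPLE["allele_frequency"][sample]
    coverage = 500  # representative depth, above the inclusion thresholds
    return MutationCall(
        sample=sample,
        gene=TP53_EXAMPLE["gene"],
        chromosome=TP53_EXAMPLE["chromosome"],
        position=TP53_EXAMPLE["position"],
        ref=TP53_EXAMPLE["ref"],
        alt=TP53_EXAMPLE["alt"],
        region_class=TP53_EXAMPLE["region_class"],
        allele_frequency=af,
        coverage=coverage,
        alt_reads=round(af * coverage),
    )


def three_lesion_case() -> list[LesionProfile]:
    """The three lesions with their published CNV events and the TP53 call.

    Pairwise identical-interval CNV sharing is 6 (bile duct, omentum),
    1 (bile duct, pancreas) and 0 (pancreas, omentum); five gene CNVs
    are shared by all three lesions.
    """
    cnvs = {
        "pancreas": _BILE_PANCREAS_SHARED + _PRIVATE["pancreas"],
        "bile_duct": _BILE_OMENTUM_SHARED
        + _BILE_PANCREAS_SHARED
        + _PRIVATE["bile_duct"],
        "omentum": _BILE_OMENTUM_SHARED + _PRIVATE["omentum"],
    }
    gene_cnvs = {
        "pancreas": _PANCREAS_GENE_CNVS,
        "bile_duct": _PANCREAS_GENE_CNVS + _EXTRA_BILE_OMENTUM,
        "omentum": _PANCREAS_GENE_CNVS + _EXTRA_BILE_OMENTUM,
    }
    lesions = []
    for lesion_id in ("pancreas", "bile_duct", "omentum"):
        lesions.append(
            LesionProfile(
                lesion_id=lesion_id,
                tissue_label=lesion_id,
                mutations=[_tp53(lesion_id)],
                cnv_intervals=[(iv, "gain") for iv in cnvs[lesion_id]],
                gene_cnvs=[
                    GeneCnvEvent(sample=lesion_id, gene=g, direction=d,
                                 log2_ratio=0.8 if d == "gain" else -0.8)
                    for g, d in gene_cnvs[lesion_id]
                ],
            )
        )
    return lesions
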