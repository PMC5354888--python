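"""Shared-event set algebra, Venn decompositions and route inference."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonorigin import (
    GenomicInterval,
    LesionProfile,
    MutationCall,
    ValidationError,
    infer_route,
    relatedness_score,
    shared_cnv_intervals,
    shared_gene_cnvs,
    shared_mutations,
    union_from_counts,
    venn_counts,
)
from clonorigin.core import GeneCnvEvent
from clonorigin.simulate import PatientSpec, generate_patient


def mutation(sample, gene="TP53", chrom="chr17", pos=7577538, ref="C", alt="T"):
    return MutationCall(sample, gene, chrom, pos, ref, alt, "exon", 0.1, 500, 50)


def lesion(lesion_id, mutations=(), intervals=(), gene_cnvs=()):
    return LesionProfile(
        lesion_id=lesion_id,
        mutations=list(mutations),
        cnv_intervals=list(intervals),
        gene_cnvs=list(gene_cnvs),
    )


class TestSharedMutations:
    def test_same_gene_and_coordinate_shared(self):
        a = lesion("a", [mutation("a")])
        b = lesion("b", [mutation("b")])
        assert shared_mutations(a, b) == {("TP53", "chr17", 7577538, "C", "T")}

    def test_same_gene_different_position_not_shared(self):
        a = lesion("a", [mutation("a", pos=100)])
        b = lesion("b", [mutation("b", pos=200)])
        assert shared_mutations(a, b) == set()

    def test_strict_mode_distinguishes_alleles(self):
        a = lesion("a", [mutation("a", alt="T")])
        b = lesion("b", [mutation("b", alt="G")])
        assert shared_mutations(a, b) == set()
        assert shared_mutations(a, b, strict=False) == {("TP53", "chr17", 7577538)}

    def test_identical_lesions_share_everything(self):
        muts = [mutation("a", pos=p) for p in (1, 2, 3)]
        a = lesion("a", muts)
        assert len(shared_mutations(a, a)) == 3


class TestSharedCnvIntervals:
    def test_identical_interval_shared(self, three_lesions):
        shared = shared_cnv_intervals(
            three_lesions["bile_duct"], three_lesions["pancreas"]
        )
        assert shared == {GenomicInterval("chrX", 177_942, 2_686_899)}

    def test_off_by_one_end_not_shared(self):
        iv1 = GenomicInterval("chr4", 143_211_964, 146_188_881)
        iv2 = GenomicInterval("chr4", 143_211_964, 146_188_880)
        a = lesion("a", intervals=[(iv1, "gain")])
        b = lesion("b", intervals=[(iv2, "gain")])
        assert shared_cnv_intervals(a, b) == set()
        # ...but a 0.99 reciprocal-overlap mode matches them
        assert shared_cnv_intervals(a, b, reciprocal_overlap=0.99) == {iv1}

    def test_disjoint_sets_empty(self, three_lesions):
        assert shared_cnv_intervals(
            three_lesions["pancreas"], three_lesions["omentum"]
        ) == set()

    def test_symmetry(self, three_lesions):
        a, b = three_lesions["bile_duct"], three_lesions["omentum"]
        assert shared_cnv_intervals(a, b) == shared_cnv_intervals(b, a)
        assert len(shared_cnv_intervals(a, b)) == 6


class TestVennCounts:
    def test_worked_union_from_tabulated_counts(self):
        assert union_from_counts([63, 84, 88], [38, 37, 46], 29) == 143

    def test_identical_lesions(self):
        muts = [mutation("x", pos=p) for p in range(1, 6)]
        lesions = [
            lesion(i, [mutation(i, pos=p) for p in range(1, 6)]) for i in "abc"
        ]
        report = venn_counts(lesions)
        assert set(report.per_lesion_mutations.values()) == {5}
        assert set(report.pairwise_shared_mutations.values()) == {5}
        assert report.triple_shared_mutations == 5
        assert report.union_size == 5

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            venn_counts([lesion("a"), lesion("a"), lesion("b")])

    @given(
        st.lists(st.sets(st.integers(0, 20)), min_size=3, max_size=3),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_brute_force_set_algebra(self, pos_sets):
        lesions = [
            lesion(f"l{i}", [mutation(f"l{i}", pos=p + 1) for p in positions])
            for i, positions in enumerate(pos_sets)
        ]
        report = venn_counts(lesions)
        A, B, C = [set(s) for s in pos_sets]
        assert report.union_size == len(A | B | C)
        assert report.triple_shared_mutations == len(A & B & C)
        assert report.pairwise_shared_mutations[("l0", "l1")] == len(A & B)
        assert report.pairwise_shared_mutations[("l1", "l2")] == len(B & C)
        # inclusion-exclusion identity holds exactly
        assert report.union_size == (
            sum(report.per_lesion_mutations.values())
            - sum(report.pairwise_shared_mutations.values())
            + report.triple_shared_mutations
        )


class TestRelatednessScore:
    def test_sum_of_components(self):
        muts = [mutation("a", pos=p) for p in range(1, 47)]
        ivs = [
            (GenomicInterval("chr1", 1000 * k, 1000 * k + 10), "gain")
            for k in range(1, 7)
        ]
        genes = [GeneCnvEvent("a", f"G{k}", "gain") for k in range(7)]
        a = lesion("a", muts, ivs, genes)
        b = lesion(
            "b",
            [mutation("b", pos=p) for p in range(1, 47)],
            ivs,
            [GeneCnvEvent("b", f"G{k}", "gain") for k in range(7)],
        )
        assert relatedness_score(a, b) == 46 + 6 + 7

    def test_disjoint_lesions_score_zero(self):
        a = lesion("a", [mutation("a", pos=1)])
        b = lesion("b", [mutation("b", pos=2)])
        assert relatedness_score(a, b) == 0

    def test_symmetric_and_self_score_is_burden(self, three_lesions):
        a, b = three_lesions["bile_duct"], three_lesions["omentum"]
        assert relatedness_score(a, b) == relatedness_score(b, a)
        assert relatedness_score(a, a) == a.event_burden


class TestInferRoute:
    def test_two_lesions_route_is_burden_order(self):
        small = lesion("origin", [mutation("origin", pos=1)])
        big = lesion(
            "met", [mutation("met", pos=p) for p in (1, 2, 3)]
        )
        ordering = infer_route([small, big])
        assert ordering.inferred_route == ["origin", "met"]
        assert ordering.burden_ranking == ["origin", "met"]

    def test_all_zero_scores_unresolved(self):
        lesions = [lesion(i, [mutation(i, pos=k)]) for k, i in enumerate("abc", 1)]
        ordering = infer_route(lesions)
        assert ordering.unresolved

    def test_generator_truth_recovered(self):
        for seed in (0, 1, 2):
            case = generate_patient(PatientSpec(seed=seed))
            ordering = infer_route(case.lesions)
            assert ordering.inferred_route == case.truth.route
            assert set(ordering.closest_pair) == {"bile_duct", "omentum"}

    def test_monotone_under_superset_growth(self):
        base = [mutation("a", pos=p) for p in range(1, 10)]
        a = lesion("a", base)
        b_small = lesion("b", [mutation("b", pos=p) for p in range(1, 5)])
        b_big = lesion("b", [mutation("b", pos=p) for p in range(1, 10)])
        assert relatedness_score(a, b_small) <= relatedness_score(a, b_big)
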