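"""Enrichment, the three-way coherence rule, and complex inference."""

import math

import pytest

from orthosig.complexes import (
    EnrichmentResult,
    PutativeComplex,
    coherent_functions,
    enrich,
    fisher_exact_greater,
    infer_complexes,
    predict_protein_functions,
)
from orthosig.mcl import ClusterSet
from orthosig.ontology import AnnotationSet


def result(term, p_corrected, k, size=4, level_dag=None):
    return EnrichmentResult(
        term=term, p_raw=p_corrected, p_corrected=p_corrected,
        k=k, cluster_size=size, K=k, N=30,
    )


class TestFisher:
    def test_perfect_enrichment_closed_form(self):
        # 3 of 3 drawn from the only 3 carriers in 30: p = 1/C(30,3)
        assert fisher_exact_greater(3, 3, 3, 30) == pytest.approx(
            1 / math.comb(30, 3), rel=1e-12
        )

    def test_saturated_term_has_p_one(self):
        assert fisher_exact_greater(5, 5, 30, 30) == 1.0

    def test_inconsistent_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_greater(4, 3, 5, 30)


class TestEnrich:
    @pytest.fixture
    def setting(self, toy_dag):
        # background of 30; 3 proteins annotated to the deep term "d"
        background = {f"q{i}" for i in range(27)} | {"p1", "p2", "p3"}
        direct = {p: {"d"} for p in ("p1", "p2", "p3")}
        ann = AnnotationSet.from_direct(direct, toy_dag)
        return background, ann, toy_dag

    def test_perfect_cluster_p_value(self, setting):
        background, ann, dag = setting
        res = enrich({"p1", "p2", "p3"}, background, ann, dag)
        by_term = {r.term: r for r in res}
        assert by_term["d"].p_raw == pytest.approx(1 / 4060, rel=1e-12)
        # all ancestors of d are carried by the same 3 proteins
        assert set(by_term) == {"d", "c", "b", "a", "root"}

    def test_bonferroni_uses_per_cluster_term_count(self, setting):
        background, ann, dag = setting
        res = enrich({"p1", "p2", "p3"}, background, ann, dag)
        m = len(res)
        for r in res:
            assert r.p_corrected == pytest.approx(min(1.0, m * r.p_raw))
            assert r.p_corrected >= r.p_raw

    def test_counts_are_consistent(self, setting):
        background, ann, dag = setting
        for r in enrich({"p1", "p2", "q0"}, background, ann, dag):
            assert r.k <= min(r.cluster_size, r.K)

    def test_empty_cluster_rejected(self, setting):
        background, ann, dag = setting
        with pytest.raises(ValueError):
            enrich(set(), background, ann, dag)

    def test_cluster_outside_background_rejected(self, setting):
        background, ann, dag = setting
        with pytest.raises(ValueError):
            enrich({"stranger"}, background, ann, dag)


class TestCoherence:
    """The three criteria are strict, exactly as printed."""

    def test_all_three_criteria_met(self, toy_dag, toy_ann):
        cluster = {"p1", "p2", "p3", "p4"}
        res = [result("d", 5e-4, k=3)]  # level(d)=4, 3 of 4 > half
        assert coherent_functions(cluster, res, toy_dag, toy_ann) == {"d"}

    def test_exactly_half_is_rejected(self, toy_dag, toy_ann):
        cluster = {"p1", "p2", "p3", "p4"}
        res = [result("d", 5e-4, k=2)]
        assert coherent_functions(cluster, res, toy_dag, toy_ann) == set()

    def test_shallow_term_rejected_despite_tiny_p(self, toy_dag, toy_ann):
        cluster = {"p1", "p2", "p3", "p4"}
        res = [result("dia", 1e-9, k=4)]  # level 3 < 4
        assert coherent_functions(cluster, res, toy_dag, toy_ann) == set()

    def test_p_equal_to_alpha_rejected(self, toy_dag, toy_ann):
        cluster = {"p1", "p2", "p3", "p4"}
        res = [result("d", 0.001, k=3)]
        assert coherent_functions(cluster, res, toy_dag, toy_ann) == set()

    def test_filial_frontier_drops_ancestors(self, toy_dag, toy_ann):
        cluster = {"p1", "p2", "p3", "p4"}
        res = [result("c", 1e-5, k=3), result("d", 1e-5, k=3)]
        # c is an ancestor of d and both pass: only the child d is filial
        # (c sits at level 3 anyway; use min_level=2 to make both eligible)
        out = coherent_functions(cluster, res, toy_dag, toy_ann, min_level=2)
        assert out == {"d"}


class TestInferComplexes:
    @pytest.fixture
    def world(self, toy_dag):
        # community of 4 proteins all annotated to the deep term d,
        # plus a coherence-free cluster, inside a background of 40
        direct = {f"m{i}": {"d"} for i in range(4)}
        direct.update({f"n{i}": {"x"} for i in range(3)})  # x is level 1
        ann = AnnotationSet.from_direct(direct, toy_dag)
        background = set(direct) | {f"bg{i}" for i in range(33)}
        cs = ClusterSet(
            clusters=[{"m0", "m1", "m2", "m3"}, {"n0", "n1", "n2"}],
            source_label="toy",
        )
        return cs, background, ann, toy_dag

    def test_only_coherent_clusters_become_complexes(self, world):
        cs, background, ann, dag = world
        cxs = infer_complexes(cs, background, ann, dag)
        assert len(cxs) == 1
        assert cxs[0].proteins == {"m0", "m1", "m2", "m3"}

    def test_full_set_inherits_ancestors_minus_root(self, world):
        cs, background, ann, dag = world
        (cx,) = infer_complexes(cs, background, ann, dag)
        assert cx.filial_functions == {"d"}
        assert cx.full_functions == {"d", "c", "b", "a"}  # root excluded

    def test_every_complex_is_sound(self, world):
        cs, background, ann, dag = world
        for cx in infer_complexes(cs, background, ann, dag):
            assert len(cx.proteins) >= 3
            assert cx.filial_functions
            assert cx.full_functions >= cx.filial_functions
            for f in cx.filial_functions:
                assert not (dag.descendants(f) & cx.filial_functions)

    def test_predictions_cover_unannotated_members(self):
        cx = PutativeComplex(
            proteins={"p1", "p2", "orphan"},
            filial_functions={"d", "dia"},
            full_functions={"d", "dia", "c"},
        )
        pred = predict_protein_functions(cx)
        assert pred["orphan"] == {"d", "dia"}
        assert set(pred) == cx.proteins

    def test_complex_requires_filial_function(self):
        with pytest.raises(ValueError):
            PutativeComplex(proteins={"a"}, filial_functions=set(), full_functions=set())
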