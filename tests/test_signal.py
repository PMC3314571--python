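"""Retrieval index, the random-sampling null, and the relatedness filters."""

import networkx as nx
import numpy as np
import pytest

from orthosig.complexes import PutativeComplex
from orthosig.config import PipelineParams
from orthosig.network import PPINetwork, ProteinSet, induce_subgraph
from orthosig.ontology import AnnotationSet
from orthosig.signal import (
    NullDistribution,
    NullResult,
    RetrievalRecord,
    build_null,
    classify_predictions,
    goslim_summarize,
    orthology_related_complexes,
    orthology_related_functions,
    percentile95,
    retrieval_index,
    retrieval_table,
    unique_complexes,
    unique_prediction_pairs,
)


def net_of(edges) -> PPINetwork:
    g = nx.Graph()
    for a, b in edges:
        g.add_edge(a, b, weight=1.0)
    return PPINetwork(g)


@pytest.fixture
def carrier_world(toy_dag):
    """Four connected carriers of the deep term d plus two non-carriers."""
    net = net_of([("c1", "c2"), ("c3", "c4"), ("o1", "o2")])
    ann = AnnotationSet.from_direct({c: {"d"} for c in ("c1", "c2", "c3", "c4")}, toy_dag)
    sub = induce_subgraph(net, ProteinSet(net.nodes, "X"))
    return net, sub, ann, toy_dag


def complex_of(*proteins, filial=("d",)):
    return PutativeComplex(
        proteins=set(proteins),
        filial_functions=set(filial),
        full_functions=set(filial),
    )


class TestRetrievalIndex:
    def test_half_of_carriers_captured(self, carrier_world):
        _, sub, ann, dag = carrier_world
        rec = retrieval_index("d", sub, [complex_of("c1", "c2")], dag, ann)
        assert (rec.numerator, rec.denominator) == (2, 4)
        assert rec.value == 0.5

    def test_full_retrieval_when_complexes_cover_background(self, carrier_world):
        _, sub, ann, dag = carrier_world
        cx = [complex_of(*sub.background)]
        for term in ("d", "c", "root"):
            rec = retrieval_index(term, sub, cx, dag, ann)
            if rec.defined:
                assert rec.value == 1.0

    def test_zero_when_no_complex_carrier(self, carrier_world):
        _, sub, ann, dag = carrier_world
        rec = retrieval_index("d", sub, [complex_of("o1", "o2")], dag, ann)
        assert rec.value == 0.0

    def test_undefined_when_background_has_no_carrier(self, carrier_world):
        net, _, ann, dag = carrier_world
        sub = induce_subgraph(net, ProteinSet({"o1", "o2"}, "noncarriers"))
        rec = retrieval_index("d", sub, [], dag, ann)
        assert not rec.defined and rec.value is None

    def test_bounds_and_monotonicity_under_added_complexes(self, carrier_world):
        _, sub, ann, dag = carrier_world
        pool = [complex_of("c1"), complex_of("c2"), complex_of("c3", "c4")]
        prev = {}
        for i in range(len(pool) + 1):
            table = retrieval_table(sub, pool[:i], dag, ann)
            for t, rec in table.items():
                assert 0.0 <= rec.value <= 1.0
                assert rec.value >= prev.get(t, 0.0)
            prev = {t: r.value for t, r in table.items()}


class TestPercentile:
    def test_rank_oracle_one_to_hundred(self):
        assert percentile95([float(v) for v in range(1, 101)]) == 95.0

    def test_ties_and_constants(self):
        assert percentile95([0.3] * 50) == 0.3
        assert percentile95([7.0]) == 7.0

    def test_matches_numpy_inverted_cdf(self):
        rng = np.random.default_rng(3)
        for n in (1, 20, 1000):
            vals = list(rng.random(n))
            expected = float(np.quantile(vals, 0.95, method="inverted_cdf"))
            assert percentile95(vals) == expected

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            percentile95([])


def rec(term, num, den, label="O"):
    return RetrievalRecord(term=term, sample_label=label, numerator=num, denominator=den)


def null_of(**thresholds):
    dists = {
        t: NullDistribution(term=t, values=[v] * 10) for t, v in thresholds.items()
    }
    return NullResult(distributions=dists, run_summaries=[], n_runs=10)


class TestRelatednessRule:
    def test_strictly_above_both_comparators(self):
        related = orthology_related_functions(
            {"f": rec("f", 6, 10)}, {"f": rec("f", 3, 10, "V")}, null_of(f=0.5)
        )
        assert related == {"f"}

    def test_equality_fails_the_strict_inequality(self):
        related = orthology_related_functions(
            {"f": rec("f", 5, 10)}, {"f": rec("f", 2, 10, "V")}, null_of(f=0.5)
        )
        assert related == set()

    def test_zero_retrieval_never_related(self):
        related = orthology_related_functions(
            {"f": rec("f", 0, 10)}, {}, null_of()
        )
        assert related == set()

    def test_undefined_ortholog_value_not_eligible(self):
        related = orthology_related_functions(
            {"f": rec("f", 0, 0)}, {}, null_of()
        )
        assert related == set()

    def test_undefined_global_value_counts_as_zero(self):
        related = orthology_related_functions(
            {"f": rec("f", 1, 10)}, {"f": rec("f", 0, 0, "V")}, null_of()
        )
        assert related == {"f"}

    def test_complexes_related_via_inherited_ancestors(self):
        cx = PutativeComplex(
            proteins={"a", "b", "c"},
            filial_functions={"leaf"},
            full_functions={"leaf", "parent"},
        )
        assert orthology_related_complexes([cx], {"parent"}) == [cx]
        assert orthology_related_complexes([cx], {"other"}) == []


class TestNull:
    def test_reproducible_and_sized(self, default_fixture):
        net, dag, ann, _, orth, _, _ = default_fixture
        params = PipelineParams(n_runs=5, seed=11)
        a = build_null(net, 20, dag, ann, params)
        b = build_null(net, 20, dag, ann, params)
        assert a.distributions.keys() == b.distributions.keys()
        for t in a.distributions:
            assert a.distributions[t].values == b.distributions[t].values
            assert len(a.distributions[t].values) == 5
        assert [s.seed for s in a.run_summaries] == list(range(11, 16))

    def test_unseen_term_has_zero_threshold(self, default_fixture):
        net, dag, ann, _, _, _, _ = default_fixture
        params = PipelineParams(n_runs=2, seed=3)
        null = build_null(net, 10, dag, ann, params)
        assert null.threshold("GO:9999999") == 0.0


class TestUniqueness:
    def gc(self):
        return [complex_of("p1", "p2", "p3", filial=("f1",))]

    def test_pair_covered_by_global_complex_not_unique(self):
        oc = complex_of("p1", "p2", "p3", filial=("f1",))
        assert unique_prediction_pairs(oc, self.gc()) == set()
        assert unique_complexes([oc], self.gc()) == []

    def test_protein_absent_from_global_class_confers_uniqueness(self):
        oc = complex_of("p1", "p9", "p3", filial=("f1",))
        assert ("p9", "f1") in unique_prediction_pairs(oc, self.gc())
        assert unique_complexes([oc], self.gc()) == [oc]

    def test_new_function_for_known_protein_confers_uniqueness(self):
        oc = complex_of("p1", "p2", "p3", filial=("f2",))
        assert unique_complexes([oc], self.gc()) == [oc]


class TestClassification:
    def test_verified_vs_novel_split(self, toy_dag):
        # reference: p1 carries d (via direct), p2 carries nothing
        reference = AnnotationSet.from_direct({"p1": {"d"}}, toy_dag)
        cx = complex_of("p1", "p2", filial=("d",))
        verified, novel = classify_predictions(cx, reference)
        assert verified == {("p1", "d")}
        assert novel == {("p2", "d")}

    def test_descendant_annotation_verifies_ancestor_prediction(self, toy_dag):
        reference = AnnotationSet.from_direct({"p1": {"d"}}, toy_dag)
        cx = complex_of("p1", filial=("c",))  # c is an ancestor of d
        verified, novel = classify_predictions(cx, reference)
        assert verified == {("p1", "c")} and novel == set()

    def test_pairs_covered_by_global_class_are_not_classified(self, toy_dag):
        reference = AnnotationSet.from_direct({"p1": {"d"}}, toy_dag)
        cx = complex_of("p1", "p2", filial=("d",))
        gc = [complex_of("p1", "p2", filial=("d",))]
        verified, novel = classify_predictions(cx, reference, gc)
        assert verified == set() and novel == set()


class TestGoSlim:
    def test_roll_up(self, toy_dag):
        # slim = {x}: dia has x among its ancestors, d does not
        out = goslim_summarize({"d", "dia", "x"}, {"x"}, toy_dag)
        assert out["x"] == {"dia", "x"}  # a slim term maps to itself
        assert out["unslimmed"] == {"d"}

    def test_multiple_slim_ancestors(self, toy_dag):
        # dia descends from both a (via b2) and x
        out = goslim_summarize({"dia"}, {"a", "x"}, toy_dag)
        assert out == {"a": {"dia"}, "x": {"dia"}}

    def test_unknown_slim_term_rejected(self, toy_dag):
        with pytest.raises(KeyError):
            goslim_summarize({"d"}, {"GO:404"}, toy_dag)
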