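import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbpln import (
    GeneSetCollection,
    NullDistribution,
    ValidationError,
    WeightedNetwork,
    bh_adjust_monotone,
    empirical_pvalue,
    geneset_null_distribution,
    network_null_distribution,
    permute_annotations,
    swap_edges,
)


def stepup_oracle(pvalues):
    """Independent Benjamini-Hochberg step-up with cumulative min from the
    largest rank down."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


class TestPermuteAnnotations:
    def test_sizes_and_coannotation_preserved(self, random_problem_factory):
        _, gs, _ = random_problem_factory(5)
        perm = permute_annotations(gs, 17)
        for name in gs.sets:
            assert len(perm.sets[name]) == len(gs.sets[name])
        for x, y in itertools.combinations(gs.processes, 2):
            assert len(perm.sets[x] & perm.sets[y]) == len(gs.sets[x] & gs.sets[y])
        for trip in itertools.combinations(gs.processes, 3):
            before = len(frozenset.intersection(*(gs.sets[t] for t in trip)))
            after = len(frozenset.intersection(*(perm.sets[t] for t in trip)))
            assert after == before
        assert perm.universe == gs.universe

    def test_single_gene_universe_unchanged(self):
        gs = GeneSetCollection({"A": frozenset({"g"}), "B": frozenset({"g"})})
        assert permute_annotations(gs, 3).sets == gs.sets

    def test_seed_determinism(self, random_problem_factory):
        _, gs, _ = random_problem_factory(6)
        assert permute_annotations(gs, 9).sets == permute_annotations(gs, 9).sets


class TestSwapEdges:
    def test_path_cannot_be_rewired(self):
        path = WeightedNetwork.from_edges([("a", "b", 1.0), ("b", "c", 0.5)])
        assert swap_edges(path, 500, 1) == path

    def test_zero_multiplier_is_identity(self, random_problem_factory):
        net, _, _ = random_problem_factory(7)
        assert swap_edges(net, 0, 1) == net

    def test_complete_graph_is_fixed(self):
        nodes = ["a", "b", "c", "d"]
        k4 = WeightedNetwork.from_edges(
            (u, v, 1.0) for u, v in itertools.combinations(nodes, 2)
        )
        assert swap_edges(k4, 200, 5) == k4

    def test_two_disjoint_edges_rewire_both_ways(self):
        net = WeightedNetwork.from_edges([("a", "b", 1.0), ("c", "d", 1.0)])
        seen = set()
        for seed in range(40):
            sw = swap_edges(net, 1, seed)
            seen.add(tuple(sorted(map(tuple, (sorted(e) for e in sw.edge_key_set())))))
        # original plus the two rewirings {(a,c),(b,d)} and {(a,d),(b,c)}
        assert (("a", "c"), ("b", "d")) in seen
        assert (("a", "d"), ("b", "c")) in seen

    def test_structure_preserved_exactly(self, random_problem_factory):
        net, _, _ = random_problem_factory(8)
        sw = swap_edges(net, 50, 123)
        assert sw.nodes == net.nodes
        assert sw.degree_sequence() == net.degree_sequence()
        assert sw.weight_multiset() == net.weight_multiset()
        for u, v, _ in sw.edges():
            assert u != v
        assert sw.edge_key_set() != net.edge_key_set()  # it did randomize


class TestNullDistributions:
    def test_single_replicate_and_determinism(self, random_problem_factory):
        net, gs, table = random_problem_factory(9)
        a, b = gs.processes[0], gs.processes[1]
        one = geneset_null_distribution(net, table, gs, a, b, 1, 4)
        assert len(one) == 1
        d1 = geneset_null_distribution(net, table, gs, a, b, 25, 4)
        d2 = geneset_null_distribution(net, table, gs, a, b, 25, 4)
        assert np.array_equal(d1.values, d2.values)
        n1 = network_null_distribution(net, table, gs, a, b, 10, 20, 4)
        n2 = network_null_distribution(net, table, gs, a, b, 10, 20, 4)
        assert np.array_equal(n1.values, n2.values)

    def test_unswappable_network_gives_degenerate_null(self, toy_scores, toy_genesets):
        net = WeightedNetwork.from_edges([("a1", "b1", 1.0)])
        null = network_null_distribution(net, toy_scores, toy_genesets, "A", "B", 20, 100, 3, normalize=False)
        assert np.all(null.values == null.values[0])
        # observed equals every null value, so the strict rule returns 0
        assert empirical_pvalue(float(null.values[0]), null) == 0.0

    def test_randomize_source_mode(self, random_problem_factory):
        net, gs, table = random_problem_factory(10)
        a, b = gs.processes[0], gs.processes[1]
        d = geneset_null_distribution(net, table, gs, a, b, 10, 4, randomize_set="source")
        assert len(d) == 10 and np.all(np.isfinite(d.values))


class TestEmpiricalPvalue:
    def test_counting(self):
        null = NullDistribution(np.arange(1.0, 11.0), "geneset", 0)
        assert empirical_pvalue(8.5, null) == pytest.approx(0.2)

    def test_observed_at_or_above_max(self):
        null = NullDistribution(np.arange(1.0, 11.0), "geneset", 0)
        assert empirical_pvalue(10.0, null) == 0.0
        assert empirical_pvalue(99.0, null) == 0.0

    def test_ties_count_as_not_larger(self):
        null = NullDistribution(np.array([5.0, 5.0, 5.0, 5.0]), "geneset", 0)
        assert empirical_pvalue(5.0, null) == 0.0

    def test_pseudo_count_variant_never_zero(self):
        null = NullDistribution(np.array([1.0, 2.0, 3.0]), "geneset", 0)
        assert empirical_pvalue(9.0, null, pseudo_count=True) == pytest.approx(0.25)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.02, 0.9], [0.015, 0.03, 0.9]),
            ([0.42], [0.42]),
        ],
    )
    def test_hand_values(self, raw, expected):
        assert bh_adjust_monotone(raw) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust_monotone([0.1, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_oracle_and_dominates_raw(self, raw):
        adj = bh_adjust_monotone(raw)
        assert adj == pytest.approx(stepup_oracle(raw), abs=1e-12)
        assert np.all(adj >= np.asarray(raw) - 1e-15)
        assert np.all(adj <= 1.0)
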