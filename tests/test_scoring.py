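import pytest

from cbpln import (
    PerturbationTable,
    WeightedNetwork,
    background_score,
    contextual_linkage_score,
    neighbor_contribution,
    neighbor_sets,
    normalized_score,
)


def naive_score(network, scores, genesets, a, b):
    """Independent oracle: double loop over all (u, v) gene pairs."""
    ga, gb = genesets.sets[a], genesets.sets[b]
    nodes = sorted(network.nodes)
    total = 0.0
    for v in nodes:
        if v in ga or v not in gb:
            continue
        best = 0.0
        adjacent_to_a = False
        for u in nodes:
            if u in ga and network.graph.has_edge(u, v):
                adjacent_to_a = True
                best = max(best, network.weight(u, v) * scores.score(u))
        if adjacent_to_a:
            total += scores.score(v) * best
    return total


class TestNeighborContribution:
    def test_maximum_over_source_neighbors(self, toy_network, toy_scores, toy_genesets):
        # b1's A-neighbors: a1 (0.8*2=1.6), a2 (0.5*1=0.5)
        assert neighbor_contribution(toy_network, toy_scores, toy_genesets, "A", "b1") == pytest.approx(1.6)

    def test_single_neighbor(self, toy_network, toy_scores, toy_genesets):
        assert neighbor_contribution(toy_network, toy_scores, toy_genesets, "A", "b2") == pytest.approx(1.0)

    def test_no_source_neighbors_is_zero(self, toy_scores, toy_genesets):
        net = WeightedNetwork.from_edges([("b1", "b2", 1.0)])
        assert neighbor_contribution(net, toy_scores, toy_genesets, "A", "b1") == 0.0


class TestContextualScore:
    def test_toy_value_and_contributions(self, toy_network, toy_scores, toy_genesets):
        s, contrib = contextual_linkage_score(toy_network, toy_scores, toy_genesets, "A", "B")
        assert s == pytest.approx(6.8)
        assert contrib["b1"] == (3.0, pytest.approx(1.6), pytest.approx(4.8))
        assert contrib["b2"] == (2.0, pytest.approx(1.0), pytest.approx(2.0))
        assert s == pytest.approx(sum(p for _, _, p in contrib.values()))

    def test_unit_reduction_to_neighbor_count(self, toy_network, toy_genesets):
        unit_net = WeightedNetwork.from_edges((u, v, 1.0) for u, v, _ in toy_network.edges())
        ones = PerturbationTable({g: 1.0 for g in unit_net.nodes})
        s, _ = contextual_linkage_score(unit_net, ones, toy_genesets, "A", "B")
        assert s == len(neighbor_sets(unit_net, toy_genesets, "A", "B").n_ab) == 2

    def test_empty_neighborhood_scores_zero(self, toy_scores, toy_genesets):
        net = WeightedNetwork.from_edges([("x", "y", 1.0)])
        s, contrib = contextual_linkage_score(net, toy_scores, toy_genesets, "A", "B")
        assert s == 0.0 and contrib == {}

    def test_matches_naive_double_loop(self, random_problem_factory):
        for seed in range(5):
            net, gs, table = random_problem_factory(seed)
            for a in gs.processes:
                for b in gs.processes:
                    if a == b:
                        continue
                    s, _ = contextual_linkage_score(net, table, gs, a, b)
                    assert s == pytest.approx(naive_score(net, table, gs, a, b), abs=1e-9)

    def test_homogeneity_in_scores_and_weights(self, toy_network, toy_scores, toy_genesets):
        s0, _ = contextual_linkage_score(toy_network, toy_scores, toy_genesets, "A", "B")
        doubled = toy_scores.scaled(2.0)
        s1, _ = contextual_linkage_score(toy_network, doubled, toy_genesets, "A", "B")
        assert s1 == pytest.approx(4.0 * s0)  # score enters twice
        heavier = WeightedNetwork.from_edges((u, v, 2.0 * w) for u, v, w in toy_network.edges())
        s2, _ = contextual_linkage_score(heavier, toy_scores, toy_genesets, "A", "B")
        assert s2 == pytest.approx(2.0 * s0)  # weight enters once

    def test_monotone_in_source_score_and_weight(self, toy_network, toy_scores, toy_genesets):
        base, _ = contextual_linkage_score(toy_network, toy_scores, toy_genesets, "A", "B")
        bumped = PerturbationTable({**toy_scores.scores, "a2": 5.0})
        up, _ = contextual_linkage_score(toy_network, bumped, toy_genesets, "A", "B")
        assert up >= base
        heavier = WeightedNetwork.from_edges(
            (u, v, w * (3.0 if {u, v} == {"a2", "b1"} else 1.0)) for u, v, w in toy_network.edges()
        )
        up2, _ = contextual_linkage_score(heavier, toy_scores, toy_genesets, "A", "B")
        assert up2 >= base


class TestBackgroundAndNormalization:
    def test_toy_background(self, toy_network, toy_scores, toy_genesets):
        # mean s over the 5 measured genes is 2.4
        assert background_score(toy_network, toy_scores, toy_genesets, "A", "B") == pytest.approx(10.368)

    def test_constant_scores_are_a_fixed_point(self, toy_network, toy_genesets):
        const = PerturbationTable({g: 1.7 for g in toy_genesets.universe})
        s, _ = contextual_linkage_score(toy_network, const, toy_genesets, "A", "B")
        bg = background_score(toy_network, const, toy_genesets, "A", "B")
        assert s == pytest.approx(bg)

    def test_empty_neighborhood_background_zero(self, toy_scores, toy_genesets):
        net = WeightedNetwork.from_edges([("x", "y", 1.0)])
        gs2 = toy_genesets
        assert background_score(net, toy_scores, gs2, "A", "B") == 0.0

    @pytest.mark.parametrize("s,bg,expected", [(6.8, 10.368, -3.568), (4.2, 4.2, 0.0), (5.0, 0.0, 5.0)])
    def test_normalized_is_difference(self, s, bg, expected):
        assert normalized_score(s, bg) == pytest.approx(expected)
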