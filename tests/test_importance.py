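"""Cohesion, node contraction, and IMC ranking against brute-force oracles."""

import math

import numpy as np
import pytest

from conftest import make_network, random_network
from _oracles import oracle_cohesion, oracle_imc

from fatiguenet.importance import (
    CohesionParams,
    cohesion,
    contract_node,
    extract_core_subnetwork,
    imc,
    node_strength,
    rank_core,
)


def as_oracle(net):
    edges = {frozenset((a, b)): w for a, b, w in net.triples}
    return net.codes, edges


class TestNodeStrength:
    def test_star_center_sums_incident_weights(self):
        net = make_network({("S", "A"): 1, ("S", "B"): 2, ("S", "C"): 3})
        assert node_strength(net, "S") == 6

    def test_isolated_node_has_zero_strength(self):
        net = make_network({("A", "B"): 1}, isolated=["Z"])
        assert node_strength(net, "Z") == 0

    def test_unit_triangle_symmetry(self, unit_triangle):
        assert [node_strength(unit_triangle, v) for v in "ABC"] == [2, 2, 2]

    def test_unknown_node_rejected(self, unit_triangle):
        with pytest.raises(KeyError):
            node_strength(unit_triangle, "Z")


class TestCohesion:
    def test_two_nodes_weight_two(self):
        net = make_network({("A", "B"): 2})
        assert cohesion(net) == 0.25

    def test_unit_triangle(self, unit_triangle):
        assert cohesion(unit_triangle) == 1 / 3

    def test_unit_path(self, unit_path):
        # s = 1 + 1 + 1 (ends 1/1, middle 2/2), l = 4/3, so 1/(3 * 4/3)
        assert cohesion(unit_path) == 0.25

    def test_single_node_is_infinite(self):
        net = make_network({}, isolated=["A"])
        assert cohesion(net) == math.inf

    def test_edgeless_and_empty_networks_rejected(self):
        with pytest.raises(ValueError, match="isolated"):
            cohesion(make_network({}, isolated=["A", "B"]))
        with pytest.raises(ValueError, match="empty"):
            cohesion(make_network({}))

    def test_typeset_variant_differs_on_weighted_path(self, unit_path):
        prose = cohesion(unit_path, CohesionParams())
        typeset = cohesion(unit_path, CohesionParams(strength_aggregation="typeset"))
        # typeset: s = 1*1 + 2*2 + 1*1 = 6, l = 4/3 -> 1/8
        assert typeset == pytest.approx(1 / 8)
        assert prose != typeset

    def test_edge_threshold_prunes_distance_graph(self):
        # path A-(5)-B-(1)-C; threshold 2 disconnects C from the rest
        net = make_network({("A", "B"): 5, ("B", "C"): 1})
        params = CohesionParams(edge_threshold=2.0)
        # s unchanged (weighted network): 5 + 6/2 + 1 = 9; l = 1 over the
        # single finite pair
        assert cohesion(net, params) == pytest.approx(1 / 9)

    def test_disconnected_policies(self):
        net = make_network({("A", "B"): 1, ("C", "D"): 1, ("D", "E"): 1})
        fin = cohesion(net, CohesionParams(disconnected_policy="finite_pairs_only"))
        # finite pairs: A-B (x2, d=1) and the path C-D-E (6 ordered pairs, total 8)
        # s = 2 + 3 = 5 over all non-isolated nodes, l = 10/8
        assert fin == pytest.approx(8 / 50)
        comp = cohesion(net, CohesionParams(disconnected_policy="component_restricted"))
        # largest component is the unit path C-D-E: cohesion 1/4
        assert comp == 0.25

    def test_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            net = random_network(rng)
            if not net.triples:
                continue
            nodes, edges = as_oracle(net)
            assert cohesion(net) == pytest.approx(
                oracle_cohesion(nodes, edges), abs=1e-12)


class TestContraction:
    def test_star_center_collapses_to_single_node(self):
        net = make_network({("S", "A"): 1, ("S", "B"): 1, ("S", "C"): 1})
        assert contract_node(net, "S").n == 1

    def test_path_middle_collapses_to_single_node(self, unit_path):
        assert contract_node(unit_path, "B").n == 1

    def test_leaf_contraction_on_weighted_path(self):
        net = make_network({("A", "B"): 2, ("B", "C"): 5})
        out = contract_node(net, "A")
        assert out.n == 2
        assert [(w) for _, _, w in out.triples] == [5.0]

    def test_parallel_edges_merge_by_summation(self):
        # contracting A merges {A,B,C}; D keeps edges to both B and C
        net = make_network({("A", "B"): 1, ("A", "C"): 1, ("B", "D"): 3, ("C", "D"): 4})
        out = contract_node(net, "A")
        assert out.n == 2
        assert out.triples[0][2] == 7.0

    def test_total_weight_conserved_outside_merged_set(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            net = random_network(rng)
            if not net.triples:
                continue
            v = net.codes[int(rng.integers(net.n))]
            merged = {v} | set(net.adjacency()[v])
            external = sum(w for a, b, w in net.triples
                           if (a in merged) != (b in merged))
            out = contract_node(net, v)
            new_code = out.codes[0]
            assert sum(w for a, b, w in out.triples
                       if new_code in (a, b)) == pytest.approx(external)

    def test_unknown_node_rejected(self, unit_path):
        with pytest.raises(KeyError):
            contract_node(unit_path, "Z")


class TestIMC:
    def test_contraction_invariant_node_scores_zero(self):
        # on the path A-(1)-B-(9)-C-(1)-D contracting the leaf A leaves the
        # cohesion unchanged (both sides evaluate to 1/20), so IMC(A) = 0
        net = make_network({("A", "B"): 1, ("B", "C"): 9, ("C", "D"): 1})
        assert imc(net, "A") == 0.0

    def test_full_collapse_scores_one(self):
        net = make_network({("S", "A"): 1, ("S", "B"): 1, ("S", "C"): 1})
        assert imc(net, "S") == 1.0

    def test_never_exceeds_one_and_star_center_dominates(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            net = random_network(rng)
            if not net.triples:
                continue
            for v in net.codes:
                assert imc(net, v) <= 1.0
        star = make_network({("S", "A"): 1, ("S", "B"): 1, ("S", "C"): 1, ("A", "B"): 1})
        assert imc(star, "S") >= max(imc(star, v) for v in "ABC")

    def test_toy_graph_matches_oracle_for_every_node(self, toy_weighted_graph):
        nodes, edges = as_oracle(toy_weighted_graph)
        for v in nodes:
            assert imc(toy_weighted_graph, v) == pytest.approx(
                oracle_imc(nodes, edges, v), abs=1e-12)

    def test_automorphic_nodes_score_equally(self, unit_triangle):
        values = {v: imc(unit_triangle, v) for v in "ABC"}
        assert len(set(values.values())) == 1

    def test_invariant_under_relabeling(self, toy_weighted_graph):
        relabeled = make_network({
            ("X1", "X2"): 3, ("X1", "X3"): 1, ("X2", "X3"): 2,
            ("X2", "X4"): 5, ("X3", "X5"): 4, ("X4", "X5"): 1,
        })
        mapping = dict(zip("ABCDE", ["X1", "X2", "X3", "X4", "X5"]))
        for old, new in mapping.items():
            assert imc(toy_weighted_graph, old) == pytest.approx(
                imc(relabeled, new), abs=1e-12)


class TestRankCore:
    def test_toy_ranking_agrees_with_oracle_sort(self, toy_weighted_graph):
        nodes, edges = as_oracle(toy_weighted_graph)
        table, core = rank_core(toy_weighted_graph, k=3)
        oracle_vals = {v: oracle_imc(nodes, edges, v) for v in nodes}
        strengths = {v: sum(w for a, b, w in toy_weighted_graph.triples if v in (a, b))
                     for v in nodes}
        expected = sorted(nodes, key=lambda v: (-oracle_vals[v], -strengths[v], v))
        assert table["node"].tolist() == expected
        assert core == expected[:3]

    def test_ranks_are_a_permutation(self, toy_weighted_graph):
        table, _ = rank_core(toy_weighted_graph, k=2)
        assert sorted(table["rank"]) == list(range(1, 6))

    def test_k_exceeding_node_count_returns_all_with_warning(self, unit_triangle, caplog):
        _, core = rank_core(unit_triangle, k=10)
        assert len(core) == 3

    def test_symmetric_nodes_get_adjacent_ranks(self, unit_triangle):
        table, _ = rank_core(unit_triangle, k=3)
        assert table["imc"].nunique() == 1
        assert table["rank"].tolist() == [1, 2, 3]


class TestCoreSubnetwork:
    def test_full_core_is_identity(self, toy_weighted_graph):
        sub = extract_core_subnetwork(toy_weighted_graph, toy_weighted_graph.codes)
        assert sub.codes == toy_weighted_graph.codes
        assert sorted(sub.triples) == sorted(toy_weighted_graph.triples)

    def test_disjoint_singletons_give_isolated_nodes(self):
        net = make_network({("A", "B"): 1, ("C", "D"): 1})
        sub, roles = extract_core_subnetwork(net, ["A"], ["C"])
        assert sub.n == 2
        assert sub.triples == []
        assert roles == {}

    def test_cross_set_edges_tagged_and_counted(self):
        rng = np.random.default_rng(9)
        net = random_network(rng, n_nodes=12)
        symptoms = [f.code for f in net.nodes if f.block == "symptom"]
        indexes = [f.code for f in net.nodes if f.block == "index"]
        sub, roles = extract_core_subnetwork(net, symptoms, indexes)
        # brute-force count of symptom-index pairs with an edge
        expected = sum(1 for a, b, _ in net.triples
                       if (a in symptoms) != (b in symptoms))
        assert sum(1 for r in roles.values() if r == "cross") == expected

    def test_unknown_core_node_rejected(self, unit_triangle):
        with pytest.raises(KeyError):
            extract_core_subnetwork(unit_triangle, ["A", "Z"])
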