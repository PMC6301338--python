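"""Omics mapping, signed heat diffusion, trajectory clustering, resizing."""

import random

import numpy as np
import pandas as pd
import pytest

from belkit.diffusion import (
    OmicsTable,
    cluster_trajectories,
    diffuse,
    map_scores,
    process_heats,
    size_by_metric,
)
from belkit.graph_model import Edge, KnowledgeNetwork, Node
from conftest import make_node, random_dag, random_network
import oracles


def gene(name):
    return Node("gene", "HGNC", name)


def bioprocess(name):
    return Node("bioprocess", "GO", name)


def build(edges):
    net = KnowledgeNetwork()
    for i, (u, rel, v) in enumerate(edges):
        net.add_edge(Edge(u, v, rel, evidence=str(i)))
    return net


class TestMapScores:
    def _net(self):
        net = KnowledgeNetwork()
        for name in ("A", "B", "C"):
            net.add_node(gene(name))
        net.add_node(bioprocess("proc"))
        return net

    def test_full_coverage(self):
        net = self._net()
        table = OmicsTable.from_rows([("HGNC", n, float(i)) for i, n in enumerate("ABC")])
        state = map_scores(net, table)
        assert state.mapped_count == 3 and state.unmatched_rows == []
        assert state.h0[gene("B")] == 1.0
        assert state.h0[bioprocess("proc")] == 0.0

    def test_foreign_genes_all_unmatched(self):
        net = self._net()
        table = OmicsTable.from_rows([("HGNC", "ZZZ", 1.0), ("MGI", "A", 2.0)])
        state = map_scores(net, table)
        assert state.mapped_count == 0
        assert len(state.unmatched_rows) == 2
        assert all(v == 0.0 for v in state.h0.values())

    def test_namespace_keyword_case_insensitive_names_sensitive(self):
        net = self._net()
        state = map_scores(net, OmicsTable.from_rows([("hgnc", "A", 2.5), ("HGNC", "a", 9.0)]))
        assert state.mapped_count == 1
        assert state.h0[gene("A")] == 2.5

    def test_known_overlap_count(self):
        rng = random.Random(0)
        net = KnowledgeNetwork()
        names = [f"G{i}" for i in range(20)]
        for name in names:
            net.add_node(gene(name))
        inside = rng.sample(names, 8)
        rows = [("HGNC", n, 1.0) for n in inside] + [("HGNC", f"X{i}", 1.0) for i in range(5)]
        assert map_scores(net, OmicsTable.from_rows(rows)).mapped_count == 8

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            map_scores(self._net(), OmicsTable.from_rows([]))

    def test_duplicate_and_nonfinite_rows_rejected(self):
        with pytest.raises(ValueError):
            OmicsTable.from_rows([("HGNC", "A", 1.0), ("HGNC", "A", 2.0)])
        with pytest.raises(ValueError):
            OmicsTable.from_rows([("HGNC", "A", float("nan"))])


class TestDiffuse:
    def _state(self, net, h0):
        base = {n: 0.0 for n in net.nodes}
        base.update(h0)
        from belkit.diffusion import HeatState

        return HeatState(h0=base, unmatched_rows=[], mapped_count=len(h0))

    def test_single_decreases_edge_flips_sign(self):
        a, b = gene("A"), bioprocess("B")
        net = build([(a, "decreases", b)])
        result = diffuse(net, self._state(net, {a: 1.0}))
        assert result.final_heat[b] == -1.0
        assert result.iterations_run == 1
        assert result.residual == 0.0

    def test_sign_product_along_chains(self):
        a, x, b = gene("A"), gene("X"), bioprocess("B")
        one_flip = build([(a, "increases", x), (x, "decreases", b)])
        result = diffuse(one_flip, self._state(one_flip, {a: 1.0}))
        assert result.final_heat[b] == -1.0
        two_flips = build([(a, "decreases", x), (x, "decreases", b)])
        result2 = diffuse(two_flips, self._state(two_flips, {a: 1.0}))
        assert result2.final_heat[b] == 1.0

    def test_net_sign_collapse_drops_contradictory_pair(self):
        a, b = gene("A"), bioprocess("B")
        net = KnowledgeNetwork()
        net.add_edge(Edge(a, b, "increases", evidence="1"))
        net.add_edge(Edge(a, b, "decreases", evidence="2"))
        result = diffuse(net, self._state(net, {a: 1.0}))
        assert result.dropped_contradictory_edges == [(a, b)]
        # a has no surviving out-edge, so it is a sink keeping its heat
        assert result.final_heat[a] == 1.0
        assert result.final_heat[b] == 0.0

    @pytest.mark.parametrize("seed", range(15))
    def test_dag_matches_path_sum_oracle(self, seed):
        net = random_dag(seed, n_nodes=random.Random(seed).randint(5, 15))
        rng = random.Random(seed + 1)
        h0 = {n: rng.uniform(-2, 2) for n in net.nodes}
        result = diffuse(net, self._state(net, h0), max_iterations=200)
        expected = oracles.path_sum_heats(net.nodes, net.edges, h0)
        for sink, value in expected.items():
            assert result.final_heat[sink] == pytest.approx(value, abs=1e-10)

    def test_linearity(self):
        net = random_dag(3)
        rng = random.Random(4)
        h1 = {n: rng.uniform(-1, 1) for n in net.nodes}
        h2 = {n: rng.uniform(-1, 1) for n in net.nodes}
        r1 = diffuse(net, self._state(net, h1))
        r2 = diffuse(net, self._state(net, h2))
        scaled = diffuse(net, self._state(net, {n: 3.0 * h1[n] for n in net.nodes}))
        summed = diffuse(net, self._state(net, {n: h1[n] + h2[n] for n in net.nodes}))
        for node in net.nodes:
            assert scaled.final_heat[node] == pytest.approx(3.0 * r1.final_heat[node], abs=1e-12)
            assert summed.final_heat[node] == pytest.approx(
                r1.final_heat[node] + r2.final_heat[node], abs=1e-12
            )

    def test_sign_symmetry_on_negated_dag(self):
        net = random_dag(5)
        flipped = KnowledgeNetwork()
        swap = {"increases": "decreases", "decreases": "increases",
                "directlyIncreases": "directlyDecreases",
                "directlyDecreases": "directlyIncreases"}
        for e in net.edges:
            flipped.add_edge(Edge(e.source, e.target, swap[e.relation], e.citation, e.evidence))
        h0 = {n: 1.0 for n in net.nodes}
        base = oracles.path_sum_heats(net.nodes, net.edges, h0)
        neg = oracles.path_sum_heats(flipped.nodes, flipped.edges, h0)
        result = diffuse(flipped, self._state(flipped, h0), max_iterations=200)
        for sink in neg:
            assert result.final_heat[sink] == pytest.approx(neg[sink], abs=1e-10)
        assert set(base) == set(neg)

    @pytest.mark.parametrize("seed", range(10))
    def test_all_positive_dag_conserves_heat(self, seed):
        net = random_dag(seed, n_nodes=10)
        positive = KnowledgeNetwork()
        for e in net.edges:
            positive.add_edge(Edge(e.source, e.target, "increases", e.citation, e.evidence))
        h0 = {n: random.Random(seed).uniform(0, 2) for n in positive.nodes}
        result = diffuse(positive, self._state(positive, h0), max_iterations=200)
        assert sum(result.absorbed.values()) == pytest.approx(sum(h0.values()), abs=1e-8)

    def test_cycles_terminate_at_max_iterations(self):
        a, b = gene("A"), gene("B")
        net = build([(a, "increases", b), (b, "increases", a)])
        result = diffuse(net, self._state(net, {a: 1.0}), max_iterations=50)
        assert result.iterations_run == 50
        assert result.residual == pytest.approx(1.0)

    def test_empty_network_is_an_error(self):
        from belkit.diffusion import HeatState

        with pytest.raises(ValueError):
            diffuse(KnowledgeNetwork(), HeatState({}, [], 0))


class TestProcessHeats:
    def test_restriction_to_bioprocess_nodes(self):
        a, b, c = gene("A"), bioprocess("B"), bioprocess("C")
        net = build([(a, "decreases", b), (a, "increases", c)])
        from belkit.diffusion import HeatState

        h0 = {n: 0.0 for n in net.nodes}
        h0[a] = 1.0
        result = diffuse(net, HeatState(h0, [], 1))
        heats = process_heats(result, net)
        assert set(heats) == {b, c}
        assert heats[b] == -0.5 and heats[c] == 0.5
        values = [abs(v) for v in heats.values()]
        assert values == sorted(values, reverse=True)

    def test_no_bioprocess_nodes_empty(self, chain_network):
        from belkit.diffusion import HeatState

        result = diffuse(chain_network, HeatState({n: 0.0 for n in chain_network.nodes}, [], 0))
        assert process_heats(result, chain_network) == {}


class TestClustering:
    def test_identical_vectors_single_cluster(self):
        heats = [{bioprocess(f"b{i}"): 1.0 for i in range(6)} for _ in range(3)]
        labels = cluster_trajectories(heats, k=5, seed=0)
        assert set(labels.values()) == {0}

    def test_two_separated_groups_recovered(self):
        rng = random.Random(0)
        group_a = [bioprocess(f"a{i}") for i in range(10)]
        group_b = [bioprocess(f"b{i}") for i in range(10)]
        heats = []
        for _ in range(3):
            hm = {}
            for node in group_a:
                hm[node] = 10.0 + rng.gauss(0, 0.1)
            for node in group_b:
                hm[node] = -10.0 + rng.gauss(0, 0.1)
            heats.append(hm)
        for seed in range(20):
            labels = cluster_trajectories(heats, k=2, seed=seed)
            assert len({labels[n] for n in group_a}) == 1
            assert len({labels[n] for n in group_b}) == 1
            assert labels[group_a[0]] != labels[group_b[0]]

    def test_deterministic_and_order_invariant(self):
        rng = random.Random(1)
        nodes = [bioprocess(f"n{i}") for i in range(12)]
        heats = [{n: rng.gauss(0, 1) for n in nodes} for _ in range(3)]
        labels1 = cluster_trajectories(heats, k=3, seed=9)
        labels2 = cluster_trajectories(heats, k=3, seed=9)
        shuffled = [dict(reversed(list(h.items()))) for h in heats]
        labels3 = cluster_trajectories(shuffled, k=3, seed=9)
        assert labels1 == labels2 == labels3

    def test_fewer_distinct_vectors_than_k(self):
        heats = [
            {bioprocess("x"): 1.0, bioprocess("y"): 1.0, bioprocess("z"): -1.0}
            for _ in range(2)
        ]
        labels = cluster_trajectories(heats, k=5, seed=0)
        assert len(set(labels.values())) == 2

    def test_bad_arguments(self):
        heats = [{bioprocess("x"): 1.0}] * 2
        with pytest.raises(ValueError):
            cluster_trajectories(heats, k=0, seed=0)
        with pytest.raises(ValueError):
            cluster_trajectories(heats[:1], k=2, seed=0)


class TestSizeByMetric:
    def test_path_graph_betweenness(self):
        a, b, c = (make_node(i) for i in range(3))
        net = build([(a, "increases", b), (b, "increases", c)])
        scores = size_by_metric(net, "betweenness")
        assert scores[b] > 0 and scores[a] == 0 and scores[c] == 0

    def test_star_center_degree(self):
        center = make_node(0)
        net = KnowledgeNetwork()
        for i in range(1, 8):
            net.add_edge(Edge(center, make_node(i), "increases", evidence=str(i)))
        assert size_by_metric(net, "degree")[center] == 7

    @pytest.mark.parametrize("seed", range(5))
    def test_betweenness_matches_path_counting(self, seed):
        net = random_network(seed, n_nodes=10, n_edges=20)
        scores = size_by_metric(net, "betweenness")
        expected = oracles.betweenness_bruteforce(net.nodes, net.edges)
        for node in net.nodes:
            assert scores[node] == pytest.approx(expected[node], abs=1e-9)

    def test_heat_metric_needs_result(self, chain_network):
        with pytest.raises(ValueError):
            size_by_metric(chain_network, "heat")
        with pytest.raises(ValueError):
            size_by_metric(chain_network, "pagerank")


class TestOmicsIO:
    def test_tsv_round_trip(self, tmp_path):
        table = OmicsTable.from_rows([("HGNC", "A", 1.5), ("HGNC", "B", -0.5)], "early")
        path = tmp_path / "omics.tsv"
        table.to_tsv(str(path))
        again = OmicsTable.from_tsv(str(path), label="early")
        pd.testing.assert_frame_equal(table.data, again.data)
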