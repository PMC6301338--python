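"""Seed methods, query transactions, replay, undo and hashing."""

import random

import pytest

from belkit.bel_io import parse_bel_document
from belkit.fixtures import CorpusSpec, generate_corpus
from belkit.graph_model import Edge, KnowledgeNetwork, compile as compile_network
from belkit.query import (
    Query,
    SeedSpec,
    apply_seed,
    query_id,
    run_query,
    seed_all_paths,
    seed_annotations,
    seed_authors,
    seed_downstream,
    seed_neighbors,
    seed_provenance,
    seed_shortest_paths,
    seed_upstream,
    undo,
)
from conftest import make_node, random_network
import oracles


def nodes_of(net):
    return net.nodes


class TestNeighbors:
    def test_chain_one_hop(self, chain_network):
        a = make_node(0)
        result = seed_neighbors(chain_network, [a], 1)
        assert result.nodes == {make_node(0), make_node(1)}

    def test_saturation_reaches_component(self, chain_network):
        result = seed_neighbors(chain_network, [make_node(0)], 3)
        assert result.nodes == chain_network.nodes
        assert result == chain_network

    def test_absent_node_error_names_it(self, chain_network):
        with pytest.raises(KeyError, match="N099"):
            seed_neighbors(chain_network, [make_node(99)], 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bfs_oracle(self, seed):
        net = random_network(seed, n_nodes=40, n_edges=70)
        rng = random.Random(seed)
        seeds = rng.sample(sorted(net.nodes), 3)
        n = rng.randint(1, 3)
        result = seed_neighbors(net, seeds, n)
        expected = oracles.bfs_within(oracles.adjacency_undirected(net.edges), seeds, n)
        assert result.nodes == expected
        # induced: every edge among the kept nodes is present
        assert {e.key() for e in result.edges} == {
            e.key() for e in net.edges
            if e.source in expected and e.target in expected
        }

    def test_all_node_seed_returns_assembly(self):
        net = random_network(1, n_nodes=15, n_edges=30)
        assert seed_neighbors(net, sorted(net.nodes), 1) == net


class TestUpDownStream:
    def test_chain_upstream_two_layers(self, chain_network):
        result = seed_upstream(chain_network, [make_node(3)])
        assert result.nodes == {make_node(1), make_node(2), make_node(3)}
        assert {(e.source, e.target) for e in result.edges} == {
            (make_node(1), make_node(2)),
            (make_node(2), make_node(3)),
        }

    def test_source_node_has_no_upstream(self, chain_network):
        result = seed_upstream(chain_network, [make_node(0)])
        assert result.nodes == {make_node(0)}
        assert result.number_of_edges() == 0

    def test_chain_downstream(self, chain_network):
        result = seed_downstream(chain_network, [make_node(0)])
        assert result.nodes == {make_node(0), make_node(1), make_node(2)}

    def test_sink_seed_downstream_is_just_seed(self, chain_network):
        result = seed_downstream(chain_network, [make_node(3)])
        assert result.nodes == {make_node(3)}

    @pytest.mark.parametrize("seed", range(10))
    def test_upstream_matches_set_algebra(self, seed):
        net = random_network(seed, n_nodes=30, n_edges=60)
        rng = random.Random(seed + 100)
        seeds = rng.sample(sorted(net.nodes), 2)
        result = seed_upstream(net, seeds)
        assert result.nodes == oracles.upstream_nodes(net.edges, seeds)
        assert all(e.is_causal for e in result.edges)

    @pytest.mark.parametrize("seed", range(10))
    def test_duality_with_reversed_graph(self, seed):
        net = random_network(seed, n_nodes=25, n_edges=50)
        reversed_net = KnowledgeNetwork()
        for node in net.nodes:
            reversed_net.add_node(node)
        for e in net.edges:
            reversed_net.add_edge(
                Edge(e.target, e.source, e.relation, e.citation, e.evidence,
                     e.annotations, e.qualifiers)
            )
        seeds = random.Random(seed).sample(sorted(net.nodes), 2)
        up = seed_upstream(net, seeds)
        down_rev = seed_downstream(reversed_net, seeds)
        assert up.nodes == down_rev.nodes
        assert {(e.target, e.source) for e in up.edges} == {
            (e.source, e.target) for e in down_rev.edges
        }


class TestPathSeeds:
    def test_shortest_path_prefers_direct_edge(self):
        net = KnowledgeNetwork()
        a, b, c = (make_node(i) for i in range(3))
        net.add_edge(Edge(a, b, "increases", evidence="1"))
        net.add_edge(Edge(b, c, "increases", evidence="2"))
        net.add_edge(Edge(a, c, "increases", evidence="3"))
        result = seed_shortest_paths(net, [a, c])
        assert result.nodes == {a, c}

    def test_disconnected_seeds_keep_only_seeds(self):
        net = KnowledgeNetwork()
        for i in range(4):
            net.add_node(make_node(i))
        result = seed_shortest_paths(net, [make_node(0), make_node(3)])
        assert result.nodes == {make_node(0), make_node(3)}
        assert result.number_of_edges() == 0

    def test_fewer_than_two_seeds_is_an_error(self, chain_network):
        with pytest.raises(ValueError):
            seed_shortest_paths(chain_network, [make_node(0)])
        with pytest.raises(ValueError):
            seed_all_paths(chain_network, [make_node(0)])

    @pytest.mark.parametrize("seed", range(10))
    def test_shortest_matches_distance_oracle(self, seed):
        net = random_network(seed, n_nodes=30, n_edges=55)
        seeds = random.Random(seed).sample(sorted(net.nodes), 3)
        result = seed_shortest_paths(net, seeds)
        assert result.nodes == oracles.shortest_path_nodes(net.edges, seeds)

    def test_all_paths_two_routes(self):
        net = KnowledgeNetwork()
        a, b, c, d, e = (make_node(i) for i in range(5))
        for i, (u, v) in enumerate([(a, b), (b, c), (a, d), (d, e), (e, c)]):
            net.add_edge(Edge(u, v, "increases", evidence=str(i)))
        result = seed_all_paths(net, [a, c])
        assert result.nodes == {a, b, c, d, e}
        assert seed_all_paths(net, [a, c], max_length=1).nodes == {a, c}

    @pytest.mark.parametrize("seed", range(8))
    def test_all_paths_matches_dfs_enumeration(self, seed):
        net = random_network(seed, n_nodes=15, n_edges=25)
        seeds = random.Random(seed).sample(sorted(net.nodes), 2)
        result = seed_all_paths(net, seeds, max_length=6)
        assert result.nodes == oracles.simple_path_nodes(net.edges, seeds, 6)


class TestFilterSeeds:
    @pytest.mark.parametrize("seed", range(5))
    def test_provenance_filter_oracle(self, seed):
        net = random_network(seed)
        refs = {e.citation.reference for e in net.edges}
        full = seed_provenance(net, refs)
        assert {e.key() for e in full.edges} == {e.key() for e in net.edges}
        assert seed_provenance(net, ["999999"]).nodes == frozenset()
        some = seed_provenance(net, ["100"])
        assert {e.key() for e in some.edges} == {
            e.key() for e in net.edges if e.citation.reference == "100"
        }

    def test_authors_case_insensitive(self):
        net = random_network(0)
        upper = seed_authors(net, ["SMITH J"])
        lower = seed_authors(net, ["smith j"])
        assert upper == lower
        assert {e.key() for e in upper.edges} == {
            e.key() for e in net.edges if "Smith J" in e.citation.authors
        }
        assert seed_authors(net, ["Nobody X"]).nodes == frozenset()

    @pytest.mark.parametrize("seed", range(5))
    def test_annotation_conjunction_matches_intersection(self, seed):
        net = random_network(seed, n_edges=60)
        both = seed_annotations(net, {"Subgraph": ["sg1"], "CellLine": ["A549"]})
        only_sg = seed_annotations(net, {"Subgraph": ["sg1"]})
        only_cl = seed_annotations(net, {"CellLine": ["A549"]})
        assert {e.key() for e in both.edges} == {
            e.key() for e in only_sg.edges
        } & {e.key() for e in only_cl.edges}

    def test_annotation_or_within_key(self):
        net = random_network(1, n_edges=60)
        union = seed_annotations(net, {"Subgraph": ["sg1", "sg2"]})
        expected = {
            e.key()
            for e in net.edges
            if e.annotations_dict().get("Subgraph", set()) & {"sg1", "sg2"}
        }
        assert {e.key() for e in union.edges} == expected


class TestRunQuery:
    def _catalog(self):
        return {"net": random_network(5, n_nodes=25, n_edges=50)}

    def test_identity_query_returns_input_byte_identically(self):
        catalog = self._catalog()
        query = Query(network_ids=["net"])
        result = run_query(query, catalog)
        assert result.to_json() == catalog["net"].to_json()

    def test_seed_union(self):
        catalog = self._catalog()
        net = catalog["net"]
        node = sorted(net.nodes)[0]
        q = Query(
            ["net"],
            seeds=[
                SeedSpec("provenance", {"pmids": ["100"]}),
                SeedSpec("neighbors", {"nodes": [node], "n": 1}),
            ],
        )
        result = run_query(q, catalog)
        part1 = seed_provenance(net, ["100"])
        part2 = seed_neighbors(net, [node], 1)
        assert result.nodes == part1.nodes | part2.nodes
        assert {e.key() for e in result.edges} == {
            e.key() for e in part1.edges
        } | {e.key() for e in part2.edges}

    def test_pipeline_equals_manual_chaining(self):
        catalog = self._catalog()
        q = Query(
            ["net"],
            seeds=[SeedSpec("annotations", {"filters": {"Subgraph": ["sg1", "sg2"]}})],
            pipeline=[("extract_causal", {}), ("collapse_to_genes", {})],
        )
        result = run_query(q, catalog)
        from belkit.transforms import collapse_to_genes, extract_causal

        manual = collapse_to_genes(
            extract_causal(
                seed_annotations(catalog["net"], {"Subgraph": ["sg1", "sg2"]})
            )
        )
        assert result == manual

    def test_replay_stability(self):
        catalog = self._catalog()
        q = Query(["net"], seeds=[SeedSpec("authors", {"names": ["Smith J"]})],
                  pipeline=[("extract_causal", {})])
        assert run_query(q, catalog).to_json() == run_query(q, catalog).to_json()

    def test_unknown_id_or_transform_fails_before_compute(self):
        catalog = self._catalog()
        with pytest.raises(KeyError):
            run_query(Query(["missing"]), catalog)
        with pytest.raises(KeyError):
            run_query(Query(["net"], pipeline=[("not_a_transform", {})]), catalog)

    def test_inputs_unmodified(self):
        catalog = self._catalog()
        before = catalog["net"].to_json()
        run_query(
            Query(["net"], seeds=[SeedSpec("provenance", {"pmids": ["100"]})],
                  pipeline=[("remove_pathologies", {})]),
            catalog,
        )
        assert catalog["net"].to_json() == before


class TestTransactions:
    def _query(self):
        return Query(
            ["net"],
            seeds=[SeedSpec("provenance", {"pmids": ["1", "2"]})],
            pipeline=[("extract_causal", {}), ("collapse_to_genes", {})],
        )

    def test_undo_pipeline_then_seeds(self):
        q = self._query()
        q1 = undo(q)
        assert [name for name, _ in q1.pipeline] == ["extract_causal"]
        q2 = undo(q1)
        assert q2.pipeline == [] and len(q2.seeds) == 1
        q3 = undo(q2)
        assert q3.seeds == [] and q3.pipeline == []
        with pytest.raises(ValueError):
            undo(q3)

    def test_undo_fully_unwinds_to_identity(self):
        q = self._query()
        for _ in range(len(q.pipeline) + len(q.seeds)):
            q = undo(q)
        assert q.seeds == [] and q.pipeline == []

    def test_query_json_round_trip(self):
        q = self._query()
        assert query_id(Query.from_json(q.to_json())) == query_id(q)

    def test_query_id_deterministic_and_discriminating(self):
        q = self._query()
        assert query_id(q) == query_id(self._query())
        other = Query(["net"], seeds=[SeedSpec("provenance", {"pmids": ["1", "3"]})],
                      pipeline=list(q.pipeline))
        assert query_id(other) != query_id(q)

    def test_query_id_invariant_under_payload_permutation(self):
        node = make_node(0)
        q1 = Query(["net"], seeds=[
            SeedSpec("annotations", {"filters": {"A": ["x", "y"], "B": ["z"]}})
        ])
        q2 = Query(["net"], seeds=[
            SeedSpec("annotations", {"filters": {"B": ["z"], "A": ["y", "x"]}})
        ])
        assert query_id(q1) == query_id(q2)

    def test_invalid_seed_specs_rejected(self):
        with pytest.raises(ValueError):
            SeedSpec("teleport", {"nodes": []})
        with pytest.raises(ValueError):
            SeedSpec("neighbors", {"nodes": [make_node(0)], "n": 0})
        with pytest.raises(ValueError):
            SeedSpec("provenance", {})


class TestSeedSubgraphProperty:
    @pytest.mark.parametrize("seed", range(5))
    def test_every_seed_result_is_a_subgraph(self, seed):
        net = random_network(seed, n_nodes=20, n_edges=40)
        nodes = random.Random(seed).sample(sorted(net.nodes), 3)
        specs = [
            SeedSpec("neighbors", {"nodes": nodes, "n": 2}),
            SeedSpec("upstream", {"nodes": nodes}),
            SeedSpec("downstream", {"nodes": nodes}),
            SeedSpec("shortest_paths", {"nodes": nodes}),
            SeedSpec("all_paths", {"nodes": nodes, "max_length": 4}),
            SeedSpec("provenance", {"pmids": ["100", "101"]}),
            SeedSpec("authors", {"names": ["Smith J"]}),
            SeedSpec("annotations", {"filters": {"Subgraph": ["sg1"]}}),
        ]
        all_keys = {e.key() for e in net.edges}
        for spec in specs:
            result = apply_seed(net, spec)
            assert result.nodes <= net.nodes
            assert {e.key() for e in result.edges} <= all_keys
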