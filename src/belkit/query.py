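"""The three-step query model: selection, seeding, transformation.

A query is a replayable transaction over a catalog of knowledge
networks: (i) the selected networks are merged into an assembly;
(ii) one or several *seed methods* extract a relevant subnetwork
(multiple seeds combine by union; no seeds keeps the whole assembly);
(iii) an ordered pipeline of registered transformations is applied.
Queries serialize losslessly to JSON, hash to a stable content
identifier, and support stepwise undo.

Seed methods
------------
``neighbors``        nodes within undirected distance N of any query node
``upstream``         two layers of causal in-edges, causal edges induced
``downstream``       two layers of causal out-edges, causal edges induced
``shortest_paths``   all nodes on all shortest directed paths between
                     query-node pairs (symmetric edges both ways)
``all_paths``        all nodes on simple directed paths of bounded length
``provenance``       edges citing the given PubMed identifiers
``authors``          edges from articles by the given authors
``annotations``      edges matching an annotation filter (OR within a
                     key, AND across keys)
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from .graph_model import Edge, KnowledgeNetwork, Node, merge_networks
from .transforms import TransformationRegistry, default_registry

__all__ = [
    "SeedSpec",
    "Query",
    "seed_neighbors",
    "seed_upstream",
    "seed_downstream",
    "seed_shortest_paths",
    "seed_all_paths",
    "seed_provenance",
    "seed_authors",
    "seed_annotations",
    "apply_seed",
    "run_query",
    "undo",
    "query_id",
]

SEED_METHODS = (
    "neighbors",
    "upstream",
    "downstream",
    "shortest_paths",
    "all_paths",
    "provenance",
    "authors",
    "annotations",
)


def _check_nodes_present(network: KnowledgeNetwork, nodes: Iterable[Node]) -> list[Node]:
    nodes = list(nodes)
    if not nodes:
        raise ValueError("seed node list is empty")
    for node in nodes:
        if node not in network:
            raise KeyError(f"query node not in network: {node.as_bel()}")
    return nodes


def seed_neighbors(
    network: KnowledgeNetwork, nodes: Iterable[Node], n: int
) -> KnowledgeNetwork:
    """Induce the subnetwork within undirected path length ≤ n of the seeds.

    Distance ignores edge direction (symmetric edges are inherently
    bidirectional); the result contains every edge among the reached
    nodes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    nodes = _check_nodes_present(network, nodes)
    und = network.undirected_view()
    reach: set[Node] = set()
    for seed in nodes:
        reach.update(nx.single_source_shortest_path_length(und, seed, cutoff=n))
    return network.induced_subgraph(reach)


def _seed_stream(
    network: KnowledgeNetwork, nodes: Iterable[Node], upstream: bool
) -> KnowledgeNetwork:
    nodes = _check_nodes_present(network, nodes)
    causal = network.directed_view(causal_only=True)
    layer = set(nodes)
    for _ in range(2):
        frontier = set()
        for node in layer:
            neighbors = causal.predecessors(node) if upstream else causal.successors(node)
            frontier.update(neighbors)
        layer |= frontier
    edges = [
        e
        for e in network.edges
        if e.is_causal and e.source in layer and e.target in layer
    ]
    out = network.subnetwork_from_edges(edges)
    for node in layer:
        out.add_node(node)
    return out


def seed_upstream(network: KnowledgeNetwork, nodes: Iterable[Node]) -> KnowledgeNetwork:
    """Two layers of causal edges targeting the query nodes.

    Layer 1 adds direct causal regulators of the seeds; layer 2 adds
    regulators of layer 1; all causal edges among the resulting nodes
    are induced.
    """
    return _seed_stream(network, nodes, upstream=True)


def seed_downstream(network: KnowledgeNetwork, nodes: Iterable[Node]) -> KnowledgeNetwork:
    """Mirror of :func:`seed_upstream` on outgoing causal edges."""
    return _seed_stream(network, nodes, upstream=False)


def seed_shortest_paths(
    network: KnowledgeNetwork, nodes: Iterable[Node]
) -> KnowledgeNetwork:
    """All nodes on all shortest directed paths between query-node pairs.

    Symmetric edges are traversable in both directions; seed pairs with
    no connecting path contribute nothing beyond the seeds themselves.
    """
    nodes = _check_nodes_present(network, nodes)
    if len(set(nodes)) < 2:
        raise ValueError("shortest_paths seeding needs at least two query nodes")
    g = network.directed_view()
    keep: set[Node] = set(nodes)
    for source in nodes:
        for target in nodes:
            if source == target:
                continue
            try:
                for path in nx.all_shortest_paths(g, source, target):
                    keep.update(path)
            except nx.NetworkXNoPath:
                continue
    return network.induced_subgraph(keep)


def seed_all_paths(
    network: KnowledgeNetwork, nodes: Iterable[Node], max_length: int = 6
) -> KnowledgeNetwork:
    """All nodes on simple directed paths of ≤ ``max_length`` edges
    between ordered seed pairs; edges among them are induced."""
    nodes = _check_nodes_present(network, nodes)
    if len(set(nodes)) < 2:
        raise ValueError("all_paths seeding needs at least two query nodes")
    g = network.directed_view()
    keep: set[Node] = set(nodes)
    for source in nodes:
        for target in nodes:
            if source == target:
                continue
            for path in nx.all_simple_paths(g, source, target, cutoff=max_length):
                keep.update(path)
    return network.induced_subgraph(keep)


def seed_provenance(
    network: KnowledgeNetwork, pmids: Iterable[str]
) -> KnowledgeNetwork:
    """Edges citing any of the given PubMed identifiers, plus endpoints."""
    wanted = {str(p) for p in pmids}
    if not wanted:
        raise ValueError("empty PubMed identifier list")
    edges = [
        e
        for e in network.edges
        if e.citation is not None
        and e.citation.db_type.lower() == "pubmed"
        and e.citation.reference in wanted
    ]
    return network.subnetwork_from_edges(edges)


def seed_authors(network: KnowledgeNetwork, names: Iterable[str]) -> KnowledgeNetwork:
    """Edges from articles by any of the given authors (exact,
    case-insensitive full-name match), plus endpoints."""
    wanted = {name.lower() for name in names}
    if not wanted:
        raise ValueError("empty author list")
    edges = [
        e
        for e in network.edges
        if e.citation is not None
        and any(a.lower() in wanted for a in e.citation.authors)
    ]
    return network.subnetwork_from_edges(edges)


def seed_annotations(
    network: KnowledgeNetwork, filters: Mapping[str, Iterable[str]]
) -> KnowledgeNetwork:
    """Edges matching the annotation filter, plus endpoints.

    Within one key the values combine by OR (any value matches); across
    keys by AND (every filter key must match).
    """
    filters = {k: set(v) for k, v in filters.items()}
    if not filters:
        raise ValueError("empty annotation filter")

    def matches(edge: Edge) -> bool:
        annotations = edge.annotations_dict()
        return all(
            key in annotations and annotations[key] & values
            for key, values in filters.items()
        )

    return network.subnetwork_from_edges([e for e in network.edges if matches(e)])


# ---------------------------------------------------------------------------
# seed specifications and transactions


@dataclass(frozen=True)
class SeedSpec:
    """One seeding step: a method name plus its method-specific payload."""

    method: str
    payload: dict

    def __post_init__(self) -> None:
        if self.method not in SEED_METHODS:
            raise ValueError(f"unknown seed method: {self.method!r}")
        if not self.payload:
            raise ValueError("seed payload must be nonempty")
        if self.method == "neighbors" and self.payload.get("n", 1) < 1:
            raise ValueError("neighbors seeding needs n >= 1")

    def to_json_dict(self) -> dict:
        payload = dict(self.payload)
        if "nodes" in payload:
            payload["nodes"] = [n.to_dict() for n in payload["nodes"]]
        if "filters" in payload:
            payload["filters"] = {k: sorted(v) for k, v in payload["filters"].items()}
        for key in ("pmids", "names"):
            if key in payload:
                payload[key] = sorted(str(v) for v in payload[key])
        return {"method": self.method, "payload": payload}

    @classmethod
    def from_json_dict(cls, data: Mapping) -> "SeedSpec":
        payload = dict(data["payload"])
        if "nodes" in payload:
            payload["nodes"] = [Node.from_dict(d) for d in payload["nodes"]]
        return cls(data["method"], payload)


def apply_seed(network: KnowledgeNetwork, spec: SeedSpec) -> KnowledgeNetwork:
    p = spec.payload
    if spec.method == "neighbors":
        return seed_neighbors(network, p["nodes"], p.get("n", 1))
    if spec.method == "upstream":
        return seed_upstream(network, p["nodes"])
    if spec.method == "downstream":
        return seed_downstream(network, p["nodes"])
    if spec.method == "shortest_paths":
        return seed_shortest_paths(network, p["nodes"])
    if spec.method == "all_paths":
        return seed_all_paths(network, p["nodes"], p.get("max_length", 6))
    if spec.method == "provenance":
        return seed_provenance(network, p["pmids"])
    if spec.method == "authors":
        return seed_authors(network, p["names"])
    if spec.method == "annotations":
        return seed_annotations(network, p["filters"])
    raise ValueError(f"unknown seed method: {spec.method!r}")  # pragma: no cover


@dataclass
class Query:
    """A replayable transaction: selection + seeds + pipeline."""

    network_ids: list[str]
    seeds: list[SeedSpec] = field(default_factory=list)
    pipeline: list[tuple[str, dict]] = field(default_factory=list)

    SCHEMA = "belkit-query/1"

    def to_json_dict(self) -> dict:
        return {
            "schema": self.SCHEMA,
            "network_ids": list(self.network_ids),
            "seeds": [s.to_json_dict() for s in self.seeds],
            "pipeline": [{"name": name, "args": args} for name, args in self.pipeline],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_json_dict(), **kwargs)

    @classmethod
    def from_json_dict(cls, data: Mapping) -> "Query":
        return cls(
            network_ids=list(data["network_ids"]),
            seeds=[SeedSpec.from_json_dict(d) for d in data.get("seeds", ())],
            pipeline=[(d["name"], dict(d.get("args", {}))) for d in data.get("pipeline", ())],
        )

    @classmethod
    def from_json(cls, text: str) -> "Query":
        return cls.from_json_dict(json.loads(text))


def run_query(
    query: Query,
    catalog: Mapping[str, KnowledgeNetwork],
    registry: Optional[TransformationRegistry] = None,
) -> KnowledgeNetwork:
    """Execute a query transaction against a network catalog.

    Validates all network ids and transformation names before computing
    anything; inputs are never modified and replaying the same query on
    the same catalog yields an identical result.
    """
    registry = registry or default_registry
    missing = [i for i in query.network_ids if i not in catalog]
    if missing:
        raise KeyError(f"unknown network id(s): {missing}")
    if not query.network_ids:
        raise ValueError("query selects no networks")
    for name, _args in query.pipeline:
        registry.get(name)

    assembly = merge_networks([catalog[i] for i in query.network_ids])

    if query.seeds:
        seeded = KnowledgeNetwork(assembly.name, assembly.version,
                                  assembly.description, assembly.metadata)
        for spec in query.seeds:
            part = apply_seed(assembly, spec)
            for node in part.nodes:
                seeded.add_node(node)
            for edge in part.edges:
                seeded.add_edge(edge)
        result = seeded
    else:
        result = assembly

    for name, args in query.pipeline:
        result = registry.apply(name, result, args, catalog=catalog)
    return result


def undo(query: Query) -> Query:
    """Revert the last step: drop the last pipeline entry, else the last
    seed; an identity query cannot be undone further."""
    if query.pipeline:
        return Query(list(query.network_ids), list(query.seeds), list(query.pipeline[:-1]))
    if query.seeds:
        return Query(list(query.network_ids), list(query.seeds[:-1]), [])
    raise ValueError("nothing to undo")


def query_id(query: Query) -> str:
    """SHA-256 content hash of the canonical JSON serialization.

    Equal queries hash equally regardless of annotation-map or value-set
    insertion order.
    """
    canonical = json.dumps(
        query.to_json_dict(), sort_keys=True, separators=(",", ":")
    )
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()
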