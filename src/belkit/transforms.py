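"""Named, pure network transformations for query pipelines.

Every transformation takes a :class:`KnowledgeNetwork` (plus arguments)
and returns a new network, never modifying its input.  Transformations
are addressed by name through a :class:`TransformationRegistry`, so query
pipelines can be stored as JSON and replayed; the module-level
``default_registry`` holds the standard set.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .graph_model import Edge, KnowledgeNetwork, Node

__all__ = [
    "Transformation",
    "TransformationRegistry",
    "default_registry",
    "extract_causal",
    "remove_pathologies",
    "delete_namespace_nodes",
    "enrich_protein_rna_origins",
    "collapse_variants",
    "collapse_to_genes",
    "enrich_members",
    "delete_node",
    "delete_edge",
    "random_subsample",
    "highlight_selection",
]


@dataclass(frozen=True)
class Transformation:
    name: str
    func: Callable[..., KnowledgeNetwork]
    schema: dict
    adds_nodes: bool = False


@dataclass
class TransformationRegistry:
    """Registry of named transformations with argument schemas."""

    entries: dict[str, Transformation] = field(default_factory=dict)

    def register(
        self,
        name: str,
        schema: Optional[dict] = None,
        adds_nodes: bool = False,
    ) -> Callable:
        def decorator(func: Callable[..., KnowledgeNetwork]) -> Callable:
            if name in self.entries:
                raise ValueError(f"transformation {name!r} already registered")
            self.entries[name] = Transformation(name, func, schema or {}, adds_nodes)
            return func

        return decorator

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return sorted(self.entries)

    def get(self, name: str) -> Transformation:
        if name not in self.entries:
            raise KeyError(f"unknown transformation: {name!r}")
        return self.entries[name]

    def apply(
        self,
        name: str,
        network: KnowledgeNetwork,
        args: Optional[dict] = None,
        catalog: Optional[dict] = None,
    ) -> KnowledgeNetwork:
        """Apply a registered transformation by name.

        Arguments declared with schema type ``"network"`` may be given as
        a catalog id (string) or a node-link dict, both resolved to a
        :class:`KnowledgeNetwork` before the call.
        """
        entry = self.get(name)
        kwargs = dict(args or {})
        for arg_name, arg_type in entry.schema.items():
            if arg_type == "network" and arg_name in kwargs:
                value = kwargs[arg_name]
                if isinstance(value, str):
                    if not catalog or value not in catalog:
                        raise KeyError(f"network argument {value!r} not in catalog")
                    kwargs[arg_name] = catalog[value]
                elif isinstance(value, dict):
                    kwargs[arg_name] = KnowledgeNetwork.from_node_link(value)
            elif arg_type == "node" and arg_name in kwargs and isinstance(kwargs[arg_name], dict):
                kwargs[arg_name] = Node.from_dict(kwargs[arg_name])
            elif arg_type == "edge" and arg_name in kwargs and isinstance(kwargs[arg_name], dict):
                kwargs[arg_name] = Edge.from_dict(kwargs[arg_name])
        return entry.func(network, **kwargs)


default_registry = TransformationRegistry()


def _rebuild(network: KnowledgeNetwork, nodes: Iterable[Node], edges: Iterable[Edge]) -> KnowledgeNetwork:
    out = KnowledgeNetwork(network.name, network.version, network.description, network.metadata)
    for node in nodes:
        out.add_node(node)
    for edge in edges:
        out.add_edge(edge)
    return out


@default_registry.register("extract_causal")
def extract_causal(network: KnowledgeNetwork) -> KnowledgeNetwork:
    """Keep only signed (causal) edges; drop nodes left isolated."""
    edges = [e for e in network.edges if e.is_causal]
    return network.subnetwork_from_edges(edges)


@default_registry.register("remove_pathologies")
def remove_pathologies(network: KnowledgeNetwork) -> KnowledgeNetwork:
    """Delete pathology nodes — often uninformative hubs — and their edges."""
    keep = {n for n in network.nodes if n.function != "pathology"}
    return network.induced_subgraph(keep)


@default_registry.register("delete_namespace_nodes", schema={"namespaces": "list"})
def delete_namespace_nodes(
    network: KnowledgeNetwork, namespaces: Iterable[str]
) -> KnowledgeNetwork:
    """Delete nodes whose namespace is in ``namespaces`` (e.g. MGI, RGD)."""
    drop = set(namespaces)
    keep = {n for n in network.nodes if n.namespace not in drop}
    return network.induced_subgraph(keep)


@default_registry.register("enrich_protein_rna_origins", adds_nodes=True)
def enrich_protein_rna_origins(network: KnowledgeNetwork) -> KnowledgeNetwork:
    """Add the central-dogma origins of every protein and RNA/miRNA node.

    For each protein, ensures the corresponding RNA and a
    ``translatedTo`` edge; then for each RNA/miRNA, ensures the
    corresponding gene and a ``transcribedTo`` edge.  Idempotent.
    """
    out = network.copy()
    for node in sorted(network.nodes):
        if node.function == "protein":
            rna = Node("rna", node.namespace, node.name)
            out.add_edge(Edge(rna, node, "translatedTo"))
    for node in sorted(out.nodes):
        if node.function in ("rna", "mirna") and not node.variants:
            gene = Node("gene", node.namespace, node.name)
            out.add_edge(Edge(gene, node, "transcribedTo"))
    return out


def _collapse(network: KnowledgeNetwork, mapping: Callable[[Node], Node],
              drop_edge: Callable[[Edge, Node, Node], bool] = lambda e, s, t: False) -> KnowledgeNetwork:
    """Quotient the network along ``mapping``, deduplicating merged edges."""
    nodes = {mapping(n) for n in network.nodes}
    edges = []
    for edge in network.edges:
        source, target = mapping(edge.source), mapping(edge.target)
        if drop_edge(edge, source, target):
            continue
        edges.append(
            Edge(source, target, edge.relation, edge.citation, edge.evidence,
                 edge.annotations, edge.qualifiers)
        )
    return _rebuild(network, nodes, edges)


@default_registry.register("collapse_variants")
def collapse_variants(network: KnowledgeNetwork) -> KnowledgeNetwork:
    """Merge every variant node into its variant-free base node."""
    return _collapse(network, lambda n: n.base)


@default_registry.register("collapse_to_genes")
def collapse_to_genes(network: KnowledgeNetwork) -> KnowledgeNetwork:
    """Collapse proteins and RNA/miRNA (and their variants) onto genes.

    Central-dogma edges (``transcribedTo``/``translatedTo``) inside a
    collapsed group are removed.  Idempotent.
    """

    def mapping(node: Node) -> Node:
        if node.function in ("protein", "rna", "mirna"):
            return Node("gene", node.namespace, node.name)
        return node.base if node.variants else node

    def drop_edge(edge: Edge, source: Node, target: Node) -> bool:
        return edge.relation in ("transcribedTo", "translatedTo") and source == target

    return _collapse(network, mapping, drop_edge)


@default_registry.register("enrich_members", schema={"resource": "network"}, adds_nodes=True)
def enrich_members(
    network: KnowledgeNetwork, resource: KnowledgeNetwork
) -> KnowledgeNetwork:
    """Add direct members/components of family and complex nodes.

    For every node of ``network`` that appears as the subject of
    ``hasMember``/``hasComponent`` edges in ``resource``, the member
    nodes and edges are added (one hop, not transitive).
    """
    out = network.copy()
    present = network.nodes
    for edge in resource.edges:
        if edge.relation in ("hasMember", "hasComponent") and edge.source in present:
            out.add_edge(edge)
    return out


@default_registry.register("delete_node", schema={"node": "node"})
def delete_node(network: KnowledgeNetwork, node: Node) -> KnowledgeNetwork:
    """Remove one node and its incident edges; absent node is an error."""
    out = network.copy()
    out.remove_node(node)
    return out


@default_registry.register("delete_edge", schema={"edge": "edge"})
def delete_edge(network: KnowledgeNetwork, edge: Edge) -> KnowledgeNetwork:
    """Remove one exact edge; absent edge is an error."""
    out = network.copy()
    out.remove_edge(edge)
    return out


@default_registry.register("random_subsample", schema={"max_nodes": "int", "seed": "int"})
def random_subsample(
    network: KnowledgeNetwork, max_nodes: int, seed: int
) -> KnowledgeNetwork:
    """Induced subgraph on a uniform node sample, deterministic given seed.

    Networks at or under ``max_nodes`` are returned unchanged (a copy).
    """
    if len(network) <= max_nodes:
        return network.copy()
    rng = random.Random(seed)
    chosen = rng.sample(sorted(network.nodes), max_nodes)
    return network.induced_subgraph(chosen)


def highlight_selection(
    network: KnowledgeNetwork,
    node_predicate: Optional[Callable[[Node], bool]] = None,
    edge_predicate: Optional[Callable[[Edge], bool]] = None,
) -> tuple[list[Node], list[Edge]]:
    """Select nodes/edges matching predicates without modifying the network."""
    nodes = [n for n in sorted(network.nodes) if node_predicate and node_predicate(n)]
    edges = [e for e in network.edges if edge_predicate and edge_predicate(e)]
    return nodes, edges
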