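"""Statistical and "biogrammar" motif summaries of knowledge networks.

The statistical summary counts nodes, edges, citations, namespaces and
annotations, and reports network-theoretic scalars: density, average node
degree, top betweenness centralities, and node overlap between networks
via the Szymkiewicz–Simpson coefficient |A∩B| / min(|A|, |B|).

The biogrammar summary searches for small curation-quality motifs:

* the *contradictory pair* — an ordered node pair curated with both an
  increasing and a decreasing causal statement (direct and indirect forms
  pooled; activity qualifiers ignored);
* the *inconsistent negative-correlation triple* — three nodes pairwise
  linked by negative correlations, which is sign-inconsistent as a cycle.

Additional two/three-node motif predicates can be registered on a
:class:`MotifRegistry` for extension.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx

from .graph_model import Edge, KnowledgeNetwork, Node

__all__ = [
    "SummaryStats",
    "MotifReport",
    "MotifRegistry",
    "network_statistics",
    "node_overlap",
    "find_contradictory_pairs",
    "find_inconsistent_negative_correlation_triples",
]


@dataclass
class SummaryStats:
    node_count: int
    edge_count: int
    citation_count: int
    function_counts: dict[str, int]
    relation_counts: dict[str, int]
    namespace_counts: dict[str, int]
    annotation_counts: dict[str, int]
    density: float
    average_degree: float
    top_centrality: dict[Node, float]

    def to_dict(self) -> dict:
        return {
            "node_count": self.node_count,
            "edge_count": self.edge_count,
            "citation_count": self.citation_count,
            "function_counts": dict(self.function_counts),
            "relation_counts": dict(self.relation_counts),
            "namespace_counts": dict(self.namespace_counts),
            "annotation_counts": dict(self.annotation_counts),
            "density": self.density,
            "average_degree": self.average_degree,
            "top_centrality": {n.as_bel(): c for n, c in self.top_centrality.items()},
        }


@dataclass
class MotifReport:
    contradictory_pairs: list[tuple[Node, Node, tuple[Edge, ...]]]
    inconsistent_triples: list[tuple[tuple[Node, Node, Node], tuple[Edge, ...]]]


def network_statistics(network: KnowledgeNetwork, top_n: int = 10) -> SummaryStats:
    """Compute the statistical summary of a network.

    Density is the fraction of connected ordered node pairs among all
    n·(n−1) ordered pairs, treating the multigraph as a simple directed
    graph; a symmetric edge connects both orders.  Average degree is
    2·|edges| / n over the edge multiset.
    """
    nodes = network.nodes
    edges = network.edges
    n = len(nodes)

    connected_pairs: set[tuple[Node, Node]] = set()
    for edge in edges:
        if edge.source == edge.target:
            continue
        connected_pairs.add((edge.source, edge.target))
        if edge.symmetric:
            connected_pairs.add((edge.target, edge.source))
    density = len(connected_pairs) / (n * (n - 1)) if n >= 2 else 0.0
    average_degree = 2 * len(edges) / n if n >= 1 else 0.0

    citations = {e.citation for e in edges if e.citation is not None}
    annotation_counts: Counter[str] = Counter()
    for edge in edges:
        for key, _values in edge.annotations:
            annotation_counts[key] += 1

    if n:
        centrality = nx.betweenness_centrality(
            _simple_directed(network), normalized=False
        )
        top = dict(
            sorted(centrality.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        )
    else:
        top = {}

    return SummaryStats(
        node_count=n,
        edge_count=len(edges),
        citation_count=len(citations),
        function_counts=dict(Counter(node.function for node in nodes)),
        relation_counts=dict(Counter(edge.relation for edge in edges)),
        namespace_counts=dict(Counter(node.namespace for node in nodes)),
        annotation_counts=dict(annotation_counts),
        density=density,
        average_degree=average_degree,
        top_centrality=top,
    )


def _simple_directed(network: KnowledgeNetwork) -> nx.DiGraph:
    """Simple directed graph; symmetric edges expanded to both arcs."""
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    for edge in network.edges:
        g.add_edge(edge.source, edge.target)
        if edge.symmetric:
            g.add_edge(edge.target, edge.source)
    return g


def node_overlap(a: KnowledgeNetwork, b: KnowledgeNetwork) -> float:
    """Szymkiewicz–Simpson overlap of the two node sets.

    Equals 1 whenever one node set contains the other; 0 when either
    network is empty.
    """
    na, nb = a.nodes, b.nodes
    if not na or not nb:
        return 0.0
    return len(na & nb) / min(len(na), len(nb))


def find_contradictory_pairs(
    network: KnowledgeNetwork,
) -> list[tuple[Node, Node, tuple[Edge, ...]]]:
    """Ordered node pairs supported by both increasing and decreasing edges.

    Direct and indirect causal forms are pooled by sign and activity
    qualifiers are ignored, so ``A increases act(B)`` contradicts
    ``A decreases act(B)``.  Output is sorted by node identity.
    """
    by_pair: dict[tuple[Node, Node], list[Edge]] = {}
    for edge in network.edges:
        if edge.is_causal:
            by_pair.setdefault((edge.source, edge.target), []).append(edge)
    out = []
    for (u, v), pair_edges in sorted(by_pair.items()):
        signs = {e.sign for e in pair_edges}
        if 1 in signs and -1 in signs:
            out.append((u, v, tuple(pair_edges)))
    return out


def find_inconsistent_negative_correlation_triples(
    network: KnowledgeNetwork,
) -> list[tuple[tuple[Node, Node, Node], tuple[Edge, ...]]]:
    """Unordered node triples pairwise linked by negative correlations.

    Each triple is reported once, nodes in sorted order, together with one
    supporting edge per pair (all supporting edges when parallel).
    """
    neg = nx.Graph()
    neg_edges: dict[frozenset[Node], list[Edge]] = {}
    for edge in network.edges:
        if edge.relation == "negativeCorrelation" and edge.source != edge.target:
            neg.add_edge(edge.source, edge.target)
            neg_edges.setdefault(frozenset((edge.source, edge.target)), []).append(edge)
    out = []
    seen: set[tuple[Node, Node, Node]] = set()
    for u, v in neg.edges():
        for w in sorted(set(neg[u]) & set(neg[v])):
            triple = tuple(sorted((u, v, w)))
            if triple in seen:
                continue
            seen.add(triple)
            a, b, c = triple
            support = tuple(
                neg_edges[frozenset(pair)][0]
                for pair in ((a, b), (b, c), (a, c))
            )
            out.append((triple, support))
    out.sort(key=lambda item: item[0])
    return out


# ---------------------------------------------------------------------------
# extensible motif registry

MotifFinder = Callable[[KnowledgeNetwork], list]


@dataclass
class MotifRegistry:
    """Named motif predicates; ships with the two built-in motifs."""

    finders: dict[str, MotifFinder] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.finders.setdefault("contradictory_pair", find_contradictory_pairs)
        self.finders.setdefault(
            "inconsistent_negative_correlation_triple",
            find_inconsistent_negative_correlation_triples,
        )

    def register(self, name: str, finder: MotifFinder) -> None:
        if name in self.finders:
            raise ValueError(f"motif {name!r} already registered")
        self.finders[name] = finder

    def find_all(self, network: KnowledgeNetwork) -> dict[str, list]:
        return {name: finder(network) for name, finder in self.finders.items()}


def motif_report(network: KnowledgeNetwork) -> MotifReport:
    return MotifReport(
        contradictory_pairs=find_contradictory_pairs(network),
        inconsistent_triples=find_inconsistent_negative_correlation_triples(network),
    )
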