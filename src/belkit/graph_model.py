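"""Directed multigraph model of causal knowledge networks.

A knowledge network is a directed multigraph whose vertices are typed
biological entities (genes, RNAs, proteins, abundances, complexes,
biological processes, pathologies, ...) and whose edges are qualified
causal or correlative relations, each carrying a citation, an evidence
string and a map of contextual annotations.

Causal relations (``increases``/``directlyIncreases`` and
``decreases``/``directlyDecreases``) carry a sign of +1 or -1; correlative
relations (``association``, ``positiveCorrelation``,
``negativeCorrelation``) are symmetric and are stored once with a
``symmetric`` flag — every traversal in this package treats them as usable
in both directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Optional

import networkx as nx

__all__ = [
    "FUNCTIONS",
    "RELATIONS",
    "CAUSAL_INCREASES",
    "CAUSAL_DECREASES",
    "SYMMETRIC_RELATIONS",
    "Node",
    "Citation",
    "Edge",
    "KnowledgeNetwork",
    "compile",
    "merge_networks",
]

#: Entity function classes a node may have.
FUNCTIONS = frozenset(
    {
        "gene",
        "rna",
        "mirna",
        "protein",
        "abundance",
        "complex",
        "composite",
        "bioprocess",
        "pathology",
    }
)

CAUSAL_INCREASES = frozenset({"increases", "directlyIncreases"})
CAUSAL_DECREASES = frozenset({"decreases", "directlyDecreases"})
SYMMETRIC_RELATIONS = frozenset({"association", "positiveCorrelation", "negativeCorrelation"})

#: The relation vocabulary.
RELATIONS = frozenset(
    {
        "increases",
        "directlyIncreases",
        "decreases",
        "directlyDecreases",
        "association",
        "positiveCorrelation",
        "negativeCorrelation",
        "hasMember",
        "hasComponent",
        "isA",
        "orthologous",
        "transcribedTo",
        "translatedTo",
    }
)

#: Functions allowed to carry variant descriptors.
_VARIANT_FUNCTIONS = frozenset({"gene", "rna", "mirna", "protein"})

_FUNCTION_TO_BEL = {
    "gene": "g",
    "rna": "r",
    "mirna": "m",
    "protein": "p",
    "abundance": "a",
    "complex": "complex",
    "composite": "composite",
    "bioprocess": "bp",
    "pathology": "path",
}

def _needs_quotes(name: str) -> bool:
    return not name.replace("_", "").isalnum() or name == ""


def _quote(name: str) -> str:
    if _needs_quotes(name):
        return '"' + name.replace('\\', '\\\\').replace('"', '\\"') + '"'
    return name


@dataclass(frozen=True, order=True)
class Node:
    """A typed biological entity; identity is the full canonical tuple.

    ``variants`` holds canonical variant descriptor strings such as
    ``pmod(Ph)`` or ``var(p.Gly12Asp)``; their order is part of identity.
    """

    function: str
    namespace: str
    name: str
    variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.function not in FUNCTIONS:
            raise ValueError(f"unknown node function: {self.function!r}")
        if self.variants and self.function not in _VARIANT_FUNCTIONS:
            raise ValueError(f"variants not allowed on {self.function} nodes")

    @property
    def base(self) -> "Node":
        """The variant-free node with the same function/namespace/name."""
        if not self.variants:
            return self
        return Node(self.function, self.namespace, self.name)

    def as_bel(self) -> str:
        inner = f"{self.namespace}:{_quote(self.name)}"
        if self.variants:
            inner += ", " + ", ".join(self.variants)
        return f"{_FUNCTION_TO_BEL[self.function]}({inner})"

    def to_dict(self) -> dict:
        return {
            "function": self.function,
            "namespace": self.namespace,
            "name": self.name,
            "variants": list(self.variants),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Node":
        return cls(
            data["function"],
            data["namespace"],
            data["name"],
            tuple(data.get("variants", ())),
        )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.as_bel()


@dataclass(frozen=True, order=True)
class Citation:
    """Provenance of a statement, typically a PubMed reference."""

    db_type: str
    reference: str
    name: str = ""
    authors: tuple[str, ...] = ()
    date: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.db_type or not self.reference:
            raise ValueError("citation db_type and reference must be nonempty")

    def to_dict(self) -> dict:
        return {
            "db_type": self.db_type,
            "reference": self.reference,
            "name": self.name,
            "authors": list(self.authors),
            "date": self.date,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Citation":
        return cls(
            data["db_type"],
            data["reference"],
            data.get("name", ""),
            tuple(data.get("authors", ())),
            data.get("date"),
        )


def _canonical_annotations(
    annotations: Mapping[str, Iterable[str]] | Iterable[tuple[str, tuple[str, ...]]] | None,
) -> tuple[tuple[str, tuple[str, ...]], ...]:
    if not annotations:
        return ()
    if isinstance(annotations, Mapping):
        items = annotations.items()
    else:
        items = annotations
    return tuple(sorted((k, tuple(sorted(set(v)))) for k, v in items))


@dataclass(frozen=True)
class Edge:
    """A directed, qualified relation between two nodes.

    ``annotations`` is stored canonically as a sorted tuple of
    ``(key, sorted value tuple)`` pairs so edges are hashable and two edges
    differing only in annotation insertion order compare equal.
    ``qualifiers`` records modifier flags such as ``subject_activity``.
    """

    source: Node
    target: Node
    relation: str
    citation: Optional[Citation] = None
    evidence: str = ""
    annotations: tuple[tuple[str, tuple[str, ...]], ...] = ()
    qualifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation: {self.relation!r}")
        object.__setattr__(self, "annotations", _canonical_annotations(self.annotations))
        object.__setattr__(self, "qualifiers", tuple(sorted(set(self.qualifiers))))

    @property
    def sign(self) -> int:
        """+1 for increasing, -1 for decreasing, 0 otherwise."""
        if self.relation in CAUSAL_INCREASES:
            return 1
        if self.relation in CAUSAL_DECREASES:
            return -1
        return 0

    @property
    def is_causal(self) -> bool:
        return self.sign != 0

    @property
    def symmetric(self) -> bool:
        return self.relation in SYMMETRIC_RELATIONS

    def annotations_dict(self) -> dict[str, set[str]]:
        return {k: set(v) for k, v in self.annotations}

    def key(self) -> tuple:
        """Total-order sort/deduplication key over every field."""
        cit = self.citation
        cit_key = ("", "", "", (), "") if cit is None else (
            cit.db_type, cit.reference, cit.name, cit.authors, cit.date or ""
        )
        return (
            self.source,
            self.target,
            self.relation,
            cit_key,
            self.evidence,
            self.annotations,
            self.qualifiers,
        )

    def to_dict(self) -> dict:
        return {
            "source": self.source.to_dict(),
            "target": self.target.to_dict(),
            "relation": self.relation,
            "citation": self.citation.to_dict() if self.citation else None,
            "evidence": self.evidence,
            "annotations": {k: sorted(v) for k, v in self.annotations},
            "qualifiers": list(self.qualifiers),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Edge":
        citation = data.get("citation")
        return cls(
            Node.from_dict(data["source"]),
            Node.from_dict(data["target"]),
            data["relation"],
            Citation.from_dict(citation) if citation else None,
            data.get("evidence", ""),
            _canonical_annotations(
                {k: tuple(v) for k, v in data.get("annotations", {}).items()}
            ),
            tuple(data.get("qualifiers", ())),
        )


class KnowledgeNetwork:
    """A directed multigraph of :class:`Node` and :class:`Edge`.

    Parallel edges between the same node pair are allowed (and common:
    the same relation curated from several articles), but exact duplicate
    edges — identical in every field — are stored once.
    """

    def __init__(
        self,
        name: str = "",
        version: str = "",
        description: str = "",
        metadata: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.name = name
        self.version = version
        self.description = description
        self.metadata: dict[str, str] = dict(metadata or {})
        self._nodes: set[Node] = set()
        self._edges: dict[tuple, Edge] = {}

    # -- construction -------------------------------------------------

    def add_node(self, node: Node) -> None:
        self._nodes.add(node)

    def add_edge(self, edge: Edge) -> None:
        self._nodes.add(edge.source)
        self._nodes.add(edge.target)
        self._edges.setdefault(edge.key(), edge)

    def remove_node(self, node: Node) -> None:
        if node not in self._nodes:
            raise KeyError(f"node not in network: {node.as_bel()}")
        self._nodes.discard(node)
        self._edges = {
            k: e for k, e in self._edges.items() if e.source != node and e.target != node
        }

    def remove_edge(self, edge: Edge) -> None:
        key = edge.key()
        if key not in self._edges:
            raise KeyError("edge not in network")
        del self._edges[key]

    # -- inspection ---------------------------------------------------

    @property
    def nodes(self) -> frozenset[Node]:
        return frozenset(self._nodes)

    @property
    def edges(self) -> tuple[Edge, ...]:
        return tuple(self._edges[k] for k in sorted(self._edges))

    def __contains__(self, node: Node) -> bool:
        return node in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def number_of_edges(self) -> int:
        return len(self._edges)

    def __iter__(self) -> Iterator[Node]:
        return iter(self._nodes)

    def __eq__(self, other: object) -> bool:
        """Structural equality: same node set and same edge set."""
        if not isinstance(other, KnowledgeNetwork):
            return NotImplemented
        return self._nodes == other._nodes and set(self._edges) == set(other._edges)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<KnowledgeNetwork {self.name!r}: {len(self._nodes)} nodes, "
            f"{len(self._edges)} edges>"
        )

    def copy(self) -> "KnowledgeNetwork":
        out = KnowledgeNetwork(self.name, self.version, self.description, self.metadata)
        out._nodes = set(self._nodes)
        out._edges = dict(self._edges)
        return out

    # -- graph views --------------------------------------------------

    def directed_view(
        self,
        causal_only: bool = False,
        expand_symmetric: bool = True,
    ) -> nx.MultiDiGraph:
        """A networkx multidigraph over the node set.

        Symmetric edges are expanded into both directions (unless
        ``expand_symmetric`` is false), so directed traversals honor their
        bidirectionality.  With ``causal_only`` only signed edges are kept.
        """
        g = nx.MultiDiGraph()
        g.add_nodes_from(self._nodes)
        for edge in self._edges.values():
            if causal_only and not edge.is_causal:
                continue
            g.add_edge(edge.source, edge.target, edge=edge, sign=edge.sign)
            if edge.symmetric and expand_symmetric:
                g.add_edge(edge.target, edge.source, edge=edge, sign=edge.sign)
        return g

    def undirected_view(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self._nodes)
        for edge in self._edges.values():
            g.add_edge(edge.source, edge.target, edge=edge)
        return g

    def induced_subgraph(self, nodes: Iterable[Node], name: str = "") -> "KnowledgeNetwork":
        """Subnetwork over ``nodes`` with every edge among them."""
        keep = set(nodes) & self._nodes
        out = KnowledgeNetwork(name or self.name, self.version, self.description, self.metadata)
        out._nodes = keep
        out._edges = {
            k: e for k, e in self._edges.items() if e.source in keep and e.target in keep
        }
        return out

    def subnetwork_from_edges(
        self, edges: Iterable[Edge], name: str = ""
    ) -> "KnowledgeNetwork":
        """Subnetwork containing exactly ``edges`` plus their endpoints."""
        out = KnowledgeNetwork(name or self.name, self.version, self.description, self.metadata)
        for edge in edges:
            out.add_edge(edge)
        return out

    def filter_edges(self, predicate: Callable[[Edge], bool]) -> list[Edge]:
        return [e for e in self.edges if predicate(e)]

    # -- serialization ------------------------------------------------

    def to_node_link(self) -> dict:
        """Stable node-link dict: nodes and edges in canonical sort order."""
        return {
            "schema": "belkit-node-link/1",
            "name": self.name,
            "version": self.version,
            "description": self.description,
            "metadata": dict(sorted(self.metadata.items())),
            "nodes": [n.to_dict() for n in sorted(self._nodes)],
            "edges": [self._edges[k].to_dict() for k in sorted(self._edges)],
        }

    @classmethod
    def from_node_link(cls, data: Mapping) -> "KnowledgeNetwork":
        out = cls(
            data.get("name", ""),
            data.get("version", ""),
            data.get("description", ""),
            data.get("metadata", {}),
        )
        for nd in data.get("nodes", ()):
            out.add_node(Node.from_dict(nd))
        for ed in data.get("edges", ()):
            out.add_edge(Edge.from_dict(ed))
        return out

    def to_json(self, **dumps_kwargs) -> str:
        dumps_kwargs.setdefault("sort_keys", True)
        dumps_kwargs.setdefault("separators", (",", ":"))
        return json.dumps(self.to_node_link(), **dumps_kwargs)

    @classmethod
    def from_json(cls, text: str) -> "KnowledgeNetwork":
        return cls.from_node_link(json.loads(text))

    def to_graphml(self, path: str) -> None:
        """Write a GraphML file for desktop network tools.

        Node identity is flattened to the BEL string; non-scalar edge
        fields are JSON-encoded since GraphML values must be scalars.
        """
        g = nx.MultiDiGraph()
        for node in sorted(self._nodes):
            g.add_node(
                node.as_bel(),
                function=node.function,
                namespace=node.namespace,
                name=node.name,
                variants=json.dumps(list(node.variants)),
            )
        for key in sorted(self._edges):
            edge = self._edges[key]
            g.add_edge(
                edge.source.as_bel(),
                edge.target.as_bel(),
                relation=edge.relation,
                sign=edge.sign,
                symmetric=edge.symmetric,
                citation=json.dumps(edge.citation.to_dict() if edge.citation else None),
                evidence=edge.evidence,
                annotations=json.dumps({k: list(v) for k, v in edge.annotations}),
            )
        nx.write_graphml(g, path)


def compile(document) -> KnowledgeNetwork:  # noqa: A001 - domain term
    """Compile a parsed BEL document into a knowledge network.

    One edge per accepted statement; nodes are deduplicated by identity.
    Activity modifiers on the subject/object become edge qualifiers
    (``subject_activity`` / ``object_activity``) on the underlying entity
    nodes, so the same node pair collects all its statements.
    """
    network = KnowledgeNetwork(
        name=document.metadata.get("Name", ""),
        version=document.metadata.get("Version", ""),
        description=document.metadata.get("Description", ""),
        metadata=dict(document.metadata),
    )
    for statement in document.statements:
        qualifiers = []
        if statement.subject.activity:
            qualifiers.append("subject_activity")
        if statement.object.activity:
            qualifiers.append("object_activity")
        network.add_edge(
            Edge(
                source=statement.subject.node,
                target=statement.object.node,
                relation=statement.relation,
                citation=statement.citation,
                evidence=statement.evidence,
                annotations=_canonical_annotations(statement.annotations),
                qualifiers=tuple(qualifiers),
            )
        )
    return network


def merge_networks(networks: list[KnowledgeNetwork]) -> KnowledgeNetwork:
    """Union of node sets and edge multisets; exact duplicates stored once.

    Merging a single network returns a metadata-preserving copy, so the
    identity query reproduces its input network exactly.
    """
    if not networks:
        raise ValueError("cannot merge an empty list of networks")
    if len(networks) == 1:
        return networks[0].copy()
    out = KnowledgeNetwork(
        name=" + ".join(n.name for n in networks if n.name),
        description="merged network",
    )
    for network in networks:
        out._nodes |= network._nodes
        for key, edge in network._edges.items():
            out._edges.setdefault(key, edge)
    return out
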