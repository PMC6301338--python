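import random

import pytest

from belkit.graph_model import Citation, Edge, KnowledgeNetwork, Node

RB1_E2F4 = """SET DOCUMENT Name = "RB1 example"
DEFINE NAMESPACE HGNC AS LIST {"RB1", "E2F4"}
SET Citation = {"PubMed", "x", "1"}
SET Evidence = "e"
p(HGNC:RB1) increases act(p(HGNC:E2F4))
p(HGNC:RB1) decreases act(p(HGNC:E2F4))
"""

_RELATIONS = (
    "increases", "increases", "decreases", "directlyIncreases",
    "directlyDecreases", "association", "positiveCorrelation",
    "negativeCorrelation", "negativeCorrelation", "isA",
)

_CITATIONS = [
    Citation("PubMed", str(ref), f"Article {ref}", authors)
    for ref, authors in [
        ("100", ("Smith J", "Jones K")),
        ("101", ("Jones K",)),
        ("102", ("Lee R", "Park S")),
        ("103", ("Park S",)),
    ]
]

_ANNOTATION_VALUES = {
    "Subgraph": ["sg1", "sg2", "sg3"],
    "CellLine": ["A549", "HEK293"],
}


def make_node(i: int, function: str = "protein") -> Node:
    return Node(function, "HGNC", f"N{i:03d}")


def random_network(
    seed: int,
    n_nodes: int = 20,
    n_edges: int = 40,
    relations=_RELATIONS,
    p_annotation: float = 0.5,
) -> KnowledgeNetwork:
    """A random knowledge network built directly (no parsing)."""
    rng = random.Random(seed)
    nodes = [make_node(i) for i in range(n_nodes)]
    net = KnowledgeNetwork(name=f"random-{seed}")
    for node in nodes:
        net.add_node(node)
    for i in range(n_edges):
        u, v = rng.sample(nodes, 2)
        annotations = {}
        for key, values in _ANNOTATION_VALUES.items():
            if rng.random() < p_annotation:
                annotations[key] = tuple(rng.sample(values, rng.randint(1, 2)))
        net.add_edge(
            Edge(
                u,
                v,
                rng.choice(relations),
                rng.choice(_CITATIONS),
                evidence=f"ev{i}",
                annotations=tuple(sorted((k, tuple(sorted(v))) for k, v in annotations.items())),
            )
        )
    return net


def random_dag(seed: int, n_nodes: int = 12, p_edge: float = 0.3) -> KnowledgeNetwork:
    """A random signed DAG (edges only from lower to higher index)."""
    rng = random.Random(seed)
    nodes = [make_node(i) for i in range(n_nodes)]
    net = KnowledgeNetwork(name=f"dag-{seed}")
    for node in nodes:
        net.add_node(node)
    k = 0
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                relation = rng.choice(
                    ("increases", "increases", "decreases", "directlyDecreases")
                )
                net.add_edge(
                    Edge(nodes[i], nodes[j], relation, _CITATIONS[0], evidence=f"d{k}")
                )
                k += 1
    return net


@pytest.fixture
def rb1_network():
    from belkit.bel_io import parse_bel_document
    from belkit.graph_model import compile as compile_network

    return compile_network(parse_bel_document(RB1_E2F4))


@pytest.fixture
def chain_network():
    """a -> b -> c -> d, all increases."""
    nodes = [make_node(i) for i in range(4)]
    net = KnowledgeNetwork(name="chain")
    for i in range(3):
        net.add_edge(Edge(nodes[i], nodes[i + 1], "increases", _CITATIONS[0], evidence=f"c{i}"))
    return net
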