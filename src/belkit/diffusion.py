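"""Sign-aware heat diffusion of omics scores over causal networks.

Differential expression scores (signed log2 fold changes) are mapped
onto gene nodes as initial heat, then propagated along causal edges.
The update is synchronous: at each step every non-sink node forwards its
entire working heat, split equally over its signed out-neighbors, and
when heat crosses a decreasing edge its sign flips.  Sink nodes — nodes
with no outgoing causal edges, notably biological processes — absorb
heat.  Parallel causal edges between a node pair are collapsed to their
net sign; pairs whose signs cancel are dropped and reported.

Iteration stops when the total circulating |heat| falls below a
tolerance or after a maximum number of steps (which bounds behavior on
cycles).  Final heats on biological-process nodes summarize which
processes the experiment dysregulates; per-stage heats can be clustered
with K-means to reveal shared progression patterns.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.cluster import KMeans

from .graph_model import KnowledgeNetwork, Node

__all__ = [
    "OmicsTable",
    "HeatState",
    "DiffusionResult",
    "map_scores",
    "diffuse",
    "process_heats",
    "cluster_trajectories",
    "size_by_metric",
]


@dataclass
class OmicsTable:
    """A scored gene table: one row per (namespace, name), finite scores."""

    data: pd.DataFrame
    label: str = ""

    COLUMNS = ("namespace", "name", "score")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"omics table missing column(s): {missing}")
        self.data = self.data.loc[:, list(self.COLUMNS)].copy()
        self.data["score"] = self.data["score"].astype(float)
        if not np.isfinite(self.data["score"]).all():
            raise ValueError("omics scores must be finite")
        if self.data.duplicated(["namespace", "name"]).any():
            raise ValueError("duplicate (namespace, name) rows in omics table")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, str, float]], label: str = ""
    ) -> "OmicsTable":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)), label)

    @classmethod
    def from_tsv(cls, path: str, label: str = "") -> "OmicsTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame, label or str(path))

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class HeatState:
    """Initial heats after mapping an omics table onto a network."""

    h0: dict[Node, float]
    unmatched_rows: list[tuple[str, str, float]]
    mapped_count: int


@dataclass
class DiffusionResult:
    final_heat: dict[Node, float]
    absorbed: dict[Node, float]
    iterations_run: int
    residual: float
    dropped_contradictory_edges: list[tuple[Node, Node]] = field(default_factory=list)


def map_scores(network: KnowledgeNetwork, omics: OmicsTable) -> HeatState:
    """Assign each omics score to the matching gene node as initial heat.

    Matching is exact on (namespace, name) with case-insensitive
    namespace keywords and case-sensitive names; only variant-free gene
    nodes are targets, so networks are best pre-processed with
    ``collapse_to_genes``.  Unmapped nodes start at heat 0; unmatched
    rows are reported.
    """
    if len(omics) == 0:
        raise ValueError("omics table is empty")
    index: dict[tuple[str, str], Node] = {}
    for node in network.nodes:
        if node.function == "gene" and not node.variants:
            index[(node.namespace.lower(), node.name)] = node
    h0: dict[Node, float] = {node: 0.0 for node in network.nodes}
    unmatched: list[tuple[str, str, float]] = []
    mapped = 0
    for namespace, name, score in omics.data.itertuples(index=False):
        node = index.get((str(namespace).lower(), str(name)))
        if node is None:
            unmatched.append((namespace, name, float(score)))
        else:
            h0[node] = float(score)
            mapped += 1
    return HeatState(h0=h0, unmatched_rows=unmatched, mapped_count=mapped)


def _collapsed_causal(
    network: KnowledgeNetwork,
) -> tuple[dict[Node, list[tuple[Node, int]]], list[tuple[Node, Node]]]:
    """Net-sign adjacency of the causal subgraph.

    Parallel causal edges between an ordered pair are summed; the pair
    keeps sign(Σ) ∈ {−1, +1}, and pairs summing to zero are dropped and
    reported as contradictory.
    """
    pair_sum: dict[tuple[Node, Node], int] = defaultdict(int)
    for edge in network.edges:
        if edge.is_causal:
            pair_sum[(edge.source, edge.target)] += edge.sign
    adjacency: dict[Node, list[tuple[Node, int]]] = defaultdict(list)
    dropped: list[tuple[Node, Node]] = []
    for (source, target), total in sorted(pair_sum.items()):
        if total == 0:
            dropped.append((source, target))
        else:
            adjacency[source].append((target, 1 if total > 0 else -1))
    return adjacency, dropped


def diffuse(
    network: KnowledgeNetwork,
    state: HeatState,
    max_iterations: int = 100,
    tolerance: float = 1e-8,
) -> DiffusionResult:
    """Run synchronous sign-aware heat diffusion to absorption.

    Each step, every node with outgoing (net-signed) causal edges
    forwards its entire working heat, split equally over those edges and
    multiplied by each edge's sign; sinks accumulate what they receive.
    Stops when total working |heat| < ``tolerance`` or after
    ``max_iterations`` steps (guaranteeing termination on cycles).
    The map is linear in the initial heats.
    """
    if len(network) == 0:
        raise ValueError("network is empty")
    adjacency, dropped = _collapsed_causal(network)
    sinks = {node for node in network.nodes if not adjacency.get(node)}

    working: dict[Node, float] = {}
    absorbed: dict[Node, float] = {}
    for node, heat in state.h0.items():
        if node not in network:
            continue
        if node in sinks:
            absorbed[node] = absorbed.get(node, 0.0) + heat
        elif heat != 0.0:
            working[node] = heat

    iterations = 0
    while iterations < max_iterations and sum(abs(h) for h in working.values()) >= tolerance:
        incoming: dict[Node, float] = defaultdict(float)
        for node, heat in working.items():
            targets = adjacency[node]
            share = heat / len(targets)
            for target, sign in targets:
                incoming[target] += share * sign
        working = {}
        for target, heat in incoming.items():
            if target in sinks:
                absorbed[target] = absorbed.get(target, 0.0) + heat
            elif heat != 0.0:
                working[target] = heat
        iterations += 1

    residual = sum(abs(h) for h in working.values())
    final_heat: dict[Node, float] = {}
    for node in network.nodes:
        if node in sinks:
            final_heat[node] = absorbed.get(node, 0.0)
        else:
            final_heat[node] = working.get(node, 0.0)
    return DiffusionResult(
        final_heat=final_heat,
        absorbed={n: absorbed.get(n, 0.0) for n in sinks},
        iterations_run=iterations,
        residual=residual,
        dropped_contradictory_edges=dropped,
    )


def process_heats(
    result: DiffusionResult, network: KnowledgeNetwork
) -> dict[Node, float]:
    """Final heats restricted to biological-process nodes, largest
    |heat| first."""
    heats = {
        node: result.final_heat.get(node, 0.0)
        for node in network.nodes
        if node.function == "bioprocess"
    }
    return dict(sorted(heats.items(), key=lambda kv: (-abs(kv[1]), kv[0])))


def cluster_trajectories(
    heats: Sequence[Mapping[Node, float]],
    k: int = 5,
    seed: int = 0,
    standardize: bool = False,
) -> dict[Node, int]:
    """K-means clustering of per-node heat trajectories across experiments.

    Each node's vector holds its final heat in every experiment (0 where
    absent).  Deterministic given ``seed``; invariant under node input
    order (rows are canonically sorted before fitting and labels are
    renumbered by first occurrence).  If fewer distinct vectors than
    ``k`` exist, fewer clusters are returned.  With ``standardize`` each
    experiment column is z-scored before clustering.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(heats) < 2:
        raise ValueError("need at least two experiments to cluster trajectories")
    nodes = sorted({node for heat_map in heats for node in heat_map})
    if not nodes:
        return {}
    matrix = np.array(
        [[float(h.get(node, 0.0)) for h in heats] for node in nodes], dtype=float
    )
    if standardize:
        std = matrix.std(axis=0)
        std[std == 0] = 1.0
        matrix = (matrix - matrix.mean(axis=0)) / std
    n_distinct = len({tuple(row) for row in matrix})
    k_eff = min(k, n_distinct)
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed % (2**31))
    raw_labels = km.fit_predict(matrix)
    relabel: dict[int, int] = {}
    for label in raw_labels:
        if label not in relabel:
            relabel[label] = len(relabel)
    return {node: relabel[label] for node, label in zip(nodes, raw_labels)}


def size_by_metric(
    network: KnowledgeNetwork,
    metric: str,
    result: Optional[DiffusionResult] = None,
) -> dict[Node, float]:
    """Node sizes for visual resizing: degree, betweenness or |heat|.

    ``degree`` counts in+out multi-edges; ``betweenness`` is shortest-path
    betweenness on the directed simple graph (symmetric edges both ways,
    unnormalized); ``heat`` requires a diffusion result.
    """
    if metric == "degree":
        sizes = {node: 0.0 for node in network.nodes}
        for edge in network.edges:
            sizes[edge.source] += 1.0
            sizes[edge.target] += 1.0
        return sizes
    if metric == "betweenness":
        g = nx.DiGraph()
        g.add_nodes_from(network.nodes)
        for edge in network.edges:
            g.add_edge(edge.source, edge.target)
            if edge.symmetric:
                g.add_edge(edge.target, edge.source)
        return dict(nx.betweenness_centrality(g, normalized=False))
    if metric == "heat":
        if result is None:
            raise ValueError("heat metric requires a diffusion result")
        return {
            node: abs(result.final_heat.get(node, 0.0)) for node in network.nodes
        }
    raise ValueError(f"unknown metric: {metric!r}")
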