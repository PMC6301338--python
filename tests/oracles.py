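"""Independent brute-force oracles used to check the library.

Everything here is deliberately naive — plain dict/set algebra and
exhaustive enumeration — and shares no code with the implementation
under test.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations


def adjacency_undirected(edges):
    """node -> set of neighbors, ignoring direction."""
    adj = defaultdict(set)
    for e in edges:
        adj[e.source].add(e.target)
        adj[e.target].add(e.source)
    return adj


def adjacency_directed(edges, causal_only=False):
    """node -> set of successors; symmetric edges go both ways."""
    adj = defaultdict(set)
    for e in edges:
        if causal_only and e.sign == 0:
            continue
        adj[e.source].add(e.target)
        if e.symmetric:
            adj[e.target].add(e.source)
    return adj


def bfs_within(adj, sources, cutoff):
    """All nodes at distance <= cutoff from any source."""
    reached = set(sources)
    frontier = set(sources)
    for _ in range(cutoff):
        frontier = {n for f in frontier for n in adj[f]} - reached
        reached |= frontier
    return reached


def bfs_distances(adj, source):
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for node in frontier:
            for neighbor in adj[node]:
                if neighbor not in dist:
                    dist[neighbor] = d
                    nxt.append(neighbor)
        frontier = nxt
    return dist


def shortest_path_nodes(edges, seeds):
    """Nodes on any shortest directed path between ordered seed pairs.

    x lies on a shortest s->t path iff d(s,x) + d(x,t) = d(s,t).
    """
    adj = adjacency_directed(edges)
    nodes = {e.source for e in edges} | {e.target for e in edges} | set(seeds)
    keep = set(seeds)
    dist_from = {s: bfs_distances(adj, s) for s in seeds}
    dist_from_any = {x: bfs_distances(adj, x) for x in nodes}
    for s in seeds:
        for t in seeds:
            if s == t or t not in dist_from[s]:
                continue
            d_st = dist_from[s][t]
            for x in nodes:
                dx = dist_from[s].get(x)
                if dx is None:
                    continue
                dxt = dist_from_any[x].get(t)
                if dxt is not None and dx + dxt == d_st:
                    keep.add(x)
    return keep


def simple_path_nodes(edges, seeds, max_length):
    """Nodes on simple directed paths of <= max_length edges between
    ordered seed pairs (exhaustive DFS)."""
    adj = adjacency_directed(edges)
    keep = set(seeds)

    def dfs(node, target, path):
        if len(path) - 1 > max_length:
            return
        if node == target and len(path) > 1:
            keep.update(path)
            return
        if len(path) - 1 == max_length:
            return
        for nxt in adj[node]:
            if nxt not in path:
                dfs(nxt, target, path + [nxt])

    for s in seeds:
        for t in seeds:
            if s != t:
                dfs(s, t, [s])
    return keep


def upstream_nodes(edges, seeds):
    preds = defaultdict(set)
    for e in edges:
        if e.sign != 0:
            preds[e.target].add(e.source)
    layer1 = set(seeds) | {u for q in seeds for u in preds[q]}
    return layer1 | {u for x in layer1 for u in preds[x]}


def contradictory_pairs_bruteforce(edges):
    """O(E^2) scan for ordered pairs with both signs."""
    pairs = set()
    causal = [e for e in edges if e.sign != 0]
    for a in causal:
        for b in causal:
            if (
                a.source == b.source
                and a.target == b.target
                and a.sign == 1
                and b.sign == -1
            ):
                pairs.add((a.source, a.target))
    return pairs


def negative_triangles_bruteforce(nodes, edges):
    """O(n^3) enumeration of all-negative correlation triangles."""
    neg = defaultdict(set)
    for e in edges:
        if e.relation == "negativeCorrelation" and e.source != e.target:
            neg[e.source].add(e.target)
            neg[e.target].add(e.source)
    triples = set()
    for a, b, c in combinations(sorted(nodes), 3):
        if b in neg[a] and c in neg[b] and a in neg[c]:
            triples.add((a, b, c))
    return triples


def density_bruteforce(nodes, edges):
    nodes = list(nodes)
    n = len(nodes)
    if n < 2:
        return 0.0
    connected = 0
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            for e in edges:
                if (e.source, e.target) == (u, v) or (
                    e.symmetric and (e.target, e.source) == (u, v)
                ):
                    connected += 1
                    break
    return connected / (n * (n - 1))


def net_sign_adjacency(edges):
    """Collapse parallel causal edges to their net sign; drop zeros."""
    sums = defaultdict(int)
    for e in edges:
        if e.sign != 0:
            sums[(e.source, e.target)] += e.sign
    adj = defaultdict(dict)
    for (u, v), total in sums.items():
        if total != 0:
            adj[u][v] = 1 if total > 0 else -1
    return adj


def path_sum_heats(nodes, edges, h0):
    """Exhaustive path-sum diffusion oracle for DAGs.

    final heat at sink = sum over all source->sink paths of
    h0(source) * prod(sign / outdeg) along the path.
    """
    adj = net_sign_adjacency(edges)
    sinks = {n for n in nodes if not adj.get(n)}
    heats = defaultdict(float)

    def walk(node, weight):
        if node in sinks:
            heats[node] += weight
            return
        targets = adj[node]
        for nxt, sign in targets.items():
            walk(nxt, weight * sign / len(targets))

    for node in nodes:
        if h0.get(node, 0.0) != 0.0:
            walk(node, h0[node])
    return {n: heats.get(n, 0.0) for n in sinks}


def betweenness_bruteforce(nodes, edges):
    """Shortest-path betweenness by exhaustive path enumeration."""
    adj = adjacency_directed(edges)
    score = {n: 0.0 for n in nodes}
    for s in nodes:
        dist = bfs_distances(adj, s)
        for t in nodes:
            if s == t or t not in dist or dist[t] == 0:
                continue
            paths = []

            def dfs(node, path):
                if len(path) - 1 > dist[t]:
                    return
                if node == t:
                    if len(path) - 1 == dist[t]:
                        paths.append(list(path))
                    return
                for nxt in adj[node]:
                    dfs(nxt, path + [nxt])

            dfs(s, [s])
            if not paths:
                continue
            for path in paths:
                for interior in path[1:-1]:
                    score[interior] += 1.0 / len(paths)
    return score
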