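"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths (and networkx's
shortest-path machinery): betweenness is recomputed from a hand-rolled BFS
with combinatorial geodesic counting, and trophic levels on acyclic webs
by bottom-up dynamic programming over a topological order.
"""

from collections import deque


def bfs_distances_and_counts(adj, source):
    """Hand-rolled BFS returning geodesic distances and path counts."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_betweenness_percent(adj):
    """Exact normalized betweenness (percent of (N-1)(N-2)/2) per node.

    For each unordered pair (s, t) and interior node v, the fraction of
    s-t geodesics through v is sigma_sv * sigma_vt / sigma_st whenever
    d(s, v) + d(v, t) = d(s, t).
    """
    nodes = sorted(adj)
    n = len(nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = bfs_distances_and_counts(adj, s)
    raw = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == d_st:
                    raw[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    denom = (n - 1) * (n - 2) / 2.0
    return {v: 100.0 * raw[v] / denom for v in nodes}


def dag_trophic_levels(web):
    """Bottom-up trophic levels on an acyclic directed web.

    Processes nodes in a topological order of the prey -> predator graph;
    requires the web to be cycle-free among consumers.
    """
    from trophoweb import identify_basal

    basal = identify_basal(web)
    levels = {}
    remaining = [n for n in web.nodes]
    # Kahn-style topological evaluation
    while remaining:
        progressed = False
        still = []
        for node in remaining:
            if node in basal:
                levels[node] = 1.0
                progressed = True
                continue
            prey = [p for p in web.prey_of(node) if p != node]
            if all(p in levels for p in prey):
                levels[node] = 1.0 + sum(levels[p] for p in prey) / len(prey)
                progressed = True
            else:
                still.append(node)
        remaining = still
        if not progressed:
            raise ValueError(f"web is not acyclic; stuck on {remaining}")
    return levels
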