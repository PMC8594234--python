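"""Brute-force reference implementations used only by the test suite.

Everything here is written from first principles (queue-based BFS, explicit
path enumeration, direct counting) so it stays independent of the library
code it checks.
"""

from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj: dict, source):
    """Hop distances from ``source`` over an adjacency dict."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_shortest_paths(adj: dict, s, t):
    """Enumerate every shortest s-t path by BFS layering + DFS."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(path)
            return
        for nxt in adj[node]:
            if dist.get(nxt) == dist[node] + 1 and dist.get(nxt, 1e9) <= dist[t]:
                walk(nxt, path + [nxt])

    walk(s, [s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def betweenness_oracle(adj: dict) -> dict:
    """Raw betweenness: fractional count of unordered pairs routed through v."""
    nodes = list(adj)
    bet = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bet[v] += through / len(paths)
    return bet


def closeness_oracle(adj: dict) -> dict:
    """Component-scaled closeness: (r / sum d) * (r / (n - 1))."""
    nodes = list(adj)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        r = len(dist) - 1
        total = sum(dist.values())
        if r == 0 or total == 0:
            out[v] = 0.0
        else:
            out[v] = (r / total) * (r / (n - 1))
    return out


def clustering_oracle(adj: dict) -> float:
    """Mean local clustering; nodes of degree < 2 contribute 0."""
    vals = []
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for a, b in combinations(sorted(nbrs), 2) if b in adj[a])
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals)) if vals else 0.0


def topology_oracle(adj: dict) -> dict:
    """Density, diameter, APL over connected pairs, component count."""
    nodes = list(adj)
    n = len(nodes)
    m = sum(len(v) for v in adj.values()) // 2
    density = 2.0 * m / (n * (n - 1)) if n >= 2 else 0.0
    diameter = 0
    dsum = 0
    pairs = 0
    for s, t in combinations(nodes, 2):
        dist = bfs_distances(adj, s)
        if t in dist:
            diameter = max(diameter, dist[t])
            dsum += dist[t]
            pairs += 1
    apl = dsum / pairs if pairs else 0.0
    seen = set()
    n_clusters = 0
    for v in nodes:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        if len(comp) >= 2:
            n_clusters += 1
    return {
        "density": density,
        "diameter": diameter,
        "avg_path_length": apl,
        "clustering_coefficient": clustering_oracle(adj),
        "n_clusters": n_clusters,
    }


def rank_oracle(values: np.ndarray) -> np.ndarray:
    """Descending average ranks by direct counting."""
    n = len(values)
    ranks = np.empty(n)
    for i, v in enumerate(values):
        greater = np.sum(values > v)
        ties = np.sum(values == v)
        # ranks occupied by the tie group: greater+1 .. greater+ties
        ranks[i] = greater + (ties + 1) / 2.0
    return ranks


def decile_labels_oracle(levins, shannon, occ, decile=0.10) -> np.ndarray:
    """Generalist/specialist labels by exhaustive rank evaluation."""
    import math

    overall = (
        rank_oracle(np.asarray(levins, float))
        + rank_oracle(np.asarray(shannon, float))
        + rank_oracle(np.asarray(occ, float))
    ) / 3.0
    n = len(overall)
    labels = np.full(n, "not_significant", dtype=object)
    if n * decile < 1.0:
        return labels
    k = math.ceil(decile * n)
    srt = np.sort(overall)
    top, bottom = srt[k - 1], srt[n - k]
    gen = overall <= top
    spec = overall >= bottom
    both = gen & spec
    labels[gen & ~both] = "generalist"
    labels[spec & ~both] = "specialist"
    return labels


def graph_to_adj(g) -> dict:
    return {v: set(g[v]) for v in g.nodes()}
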