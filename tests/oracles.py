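"""Independent brute-force oracles for the centrality measures.

Everything here works by explicit enumeration (all simple paths, all vertex
subsets, recursive tree walks) and never calls the package's own
implementations, so it is only usable on tiny graphs (<= ~8 nodes).
"""

from __future__ import annotations

import math
from itertools import combinations


def _adj(nodes, edges):
    a = {v: set() for v in nodes}
    for u, w in edges:
        a[u].add(w)
        a[w].add(u)
    return a


def enumerate_simple_paths(nodes, edges, s, t):
    """All simple s-t paths by exhaustive DFS."""
    adj = _adj(nodes, edges)
    paths = []

    def walk(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for w in adj[u]:
            if w not in path:
                walk(path + [w])

    walk([s])
    return paths


def shortest_paths(nodes, edges, s, t):
    """(distance, list of shortest simple paths); (inf, []) if unreachable."""
    paths = enumerate_simple_paths(nodes, edges, s, t)
    if not paths:
        return math.inf, []
    d = min(len(p) - 1 for p in paths)
    return d, [p for p in paths if len(p) - 1 == d]


def all_pairs(nodes, edges):
    out = {}
    for s, t in combinations(nodes, 2):
        out[(s, t)] = shortest_paths(nodes, edges, s, t)
    return out


def reachable_from(nodes, edges, s):
    adj = _adj(nodes, edges)
    seen = {s}
    stack = [s]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def oracle_degree(nodes, edges):
    adj = _adj(nodes, edges)
    return {v: float(len(adj[v])) for v in nodes}


def oracle_closeness(nodes, edges):
    ap = all_pairs(nodes, edges)
    out = {v: 0.0 for v in nodes}
    for (s, t), (d, _) in ap.items():
        if math.isfinite(d) and d > 0:
            out[s] += 1.0 / d
            out[t] += 1.0 / d
    return out


def oracle_betweenness(nodes, edges):
    ap = all_pairs(nodes, edges)
    out = {v: 0.0 for v in nodes}
    for (s, t), (d, paths) in ap.items():
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out


def oracle_stress(nodes, edges):
    ap = all_pairs(nodes, edges)
    out = {v: 0.0 for v in nodes}
    for (s, t), (_, paths) in ap.items():
        for v in nodes:
            if v in (s, t):
                continue
            out[v] += sum(1 for p in paths if v in p)
    return out


def oracle_eccentricity(nodes, edges):
    out = {}
    for v in nodes:
        dists = []
        for w in nodes:
            if w == v:
                continue
            d, _ = shortest_paths(nodes, edges, v, w)
            if math.isfinite(d):
                dists.append(d)
        out[v] = 1.0 / max(dists) if dists else 0.0
    return out


def oracle_radiality(nodes, edges):
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    if n < 2:
        return out
    for v in nodes:
        comp = reachable_from(nodes, edges, v)
        if len(comp) == 1:
            continue
        diam = max(
            shortest_paths(nodes, edges, a, b)[0]
            for a, b in combinations(sorted(comp), 2)
        )
        total = 0.0
        for w in comp:
            if w == v:
                continue
            d, _ = shortest_paths(nodes, edges, v, w)
            total += diam + 1 - d
        out[v] = total / (n - 1)
    return out


def oracle_mnc(nodes, edges):
    adj = _adj(nodes, edges)
    out = {}
    for v in nodes:
        nbrs = sorted(adj[v])
        sub_edges = [(a, b) for a, b in edges if a in adj[v] and b in adj[v]]
        best = 0
        for u in nbrs:
            best = max(best, len(reachable_from(nbrs, sub_edges, u)))
        out[v] = float(best)
    return out


def _is_clique(subset, adj):
    return all(b in adj[a] for a, b in combinations(subset, 2))


def oracle_mcc(nodes, edges):
    adj = _adj(nodes, edges)
    cliques = []
    for k in range(2, len(nodes) + 1):
        for subset in combinations(sorted(nodes), k):
            if _is_clique(subset, adj):
                cliques.append(set(subset))
    maximal = [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]
    out = {v: 0.0 for v in nodes}
    for c in maximal:
        w = math.factorial(len(c) - 1)
        for v in c:
            out[v] += w
    return out


def oracle_bottleneck(nodes, edges):
    """Recursive descendant counting over deterministic BFS trees."""
    adj = _adj(nodes, edges)
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    for s in nodes:
        children = {v: [] for v in nodes}
        seen = {s}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(adj[u]):
                    if w not in seen:
                        seen.add(w)
                        children[u].append(w)
                        nxt.append(w)
            frontier = nxt

        def count(v):
            return 1 + sum(count(c) for c in children[v])

        for v in seen:
            if count(v) > n / 4.0:
                out[v] += 1.0
    return out


def oracle_component_size(nodes, edges):
    return {v: float(len(reachable_from(nodes, edges, v))) for v in nodes}
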