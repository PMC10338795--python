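"""Consensus hub-gene detection on protein-protein interaction networks.

Ten node-centrality measures (the CytoHubba set: MCC, MNC, EPC, Betweenness,
BottleNeck, Closeness, Degree, EcCentricity, Radiality, Stress) are computed
on a simple undirected graph, each method's top fraction of nodes is taken
(ceil rounding, ties broken by ascending node label), and the consensus hub
set is the intersection of the ten top sets.

Definitions used here:

* Degree(v) = |N(v)|
* Closeness(v) = sum over reachable w != v of 1/d(v, w)  (harmonic closeness,
  well-defined on disconnected graphs)
* Betweenness(v) = sum over unordered pairs {s, t} (s,t != v) of
  sigma_st(v)/sigma_st
* Stress(v) = sum over unordered pairs of sigma_st(v), the number of shortest
  s-t paths passing through v
* EcCentricity(v) = 1 / max over reachable w of d(v, w); 0 for isolated nodes
* Radiality(v) = sum over reachable w != v of (diam_C + 1 - d(v, w)) / (n - 1),
  with diam_C the diameter of v's connected component and n the graph order
* MNC(v) = size of the largest connected component of the subgraph induced on
  N(v)
* MCC(v) = sum over maximal cliques C containing v (|C| >= 2) of (|C| - 1)!;
  0 for isolated nodes
* BottleNeck(v) = number of roots s whose deterministic BFS tree (neighbors
  visited in ascending label order) gives v a subtree containing more than
  n/4 nodes (the subtree includes v itself)
* EPC(v) = mean over seeded random edge-retention realizations (each edge kept
  independently with probability ``epc_keep_prob``) of the size of v's
  connected component
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "CENTRALITY_METHODS",
    "compute_centrality",
    "centrality_table",
    "rank_top_fraction",
    "HubConsensus",
    "consensus_hubs",
]

CENTRALITY_METHODS = (
    "MCC",
    "MNC",
    "EPC",
    "Betweenness",
    "BottleNeck",
    "Closeness",
    "Degree",
    "EcCentricity",
    "Radiality",
    "Stress",
)


# ---------------------------------------------------------------------------
# shortest-path machinery shared by Stress / EcCentricity / Radiality
# ---------------------------------------------------------------------------

def _bfs_dist_sigma(g: nx.Graph, nodes: list):
    """All-pairs hop distances and shortest-path counts via BFS per source."""
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0
        sigma[si, si] = 1.0
        q = deque([s])
        while q:
            u = q.popleft()
            ui = idx[u]
            for w in g[u]:
                wi = idx[w]
                if np.isinf(dist[si, wi]):
                    dist[si, wi] = dist[si, ui] + 1
                    q.append(w)
                if dist[si, wi] == dist[si, ui] + 1:
                    sigma[si, wi] += sigma[si, ui]
    return dist, sigma


def _stress(g: nx.Graph) -> dict:
    nodes = sorted(g.nodes)
    n = len(nodes)
    dist, sigma = _bfs_dist_sigma(g, nodes)
    out = {}
    finite = np.isfinite(dist)
    for vi, v in enumerate(nodes):
        # paths s -> v -> t: sigma_sv * sigma_vt where distances add up
        through = (dist[:, vi][:, None] + dist[vi, :][None, :]) == dist
        through &= finite
        weight = sigma[:, vi][:, None] * sigma[vi, :][None, :]
        total = through * weight
        total[vi, :] = 0
        total[:, vi] = 0
        np.fill_diagonal(total, 0)
        out[v] = float(total.sum() / 2.0)  # unordered pairs
    return out


def _eccentricity_scores(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        lengths.pop(v, None)
        out[v] = 1.0 / max(lengths.values()) if lengths else 0.0
    return out


def _radiality(g: nx.Graph) -> dict:
    n = g.number_of_nodes()
    out = {v: 0.0 for v in g.nodes}
    if n < 2:
        return out
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() == 1:
            continue
        ecc = nx.eccentricity(sub)
        diam = max(ecc.values())
        for v in comp:
            lengths = nx.single_source_shortest_path_length(sub, v)
            lengths.pop(v, None)
            out[v] = sum(diam + 1 - d for d in lengths.values()) / (n - 1)
    return out


def _mnc(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes:
        nbrs = list(g[v])
        if not nbrs:
            out[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        out[v] = float(max(len(c) for c in nx.connected_components(sub)))
    return out


def _mcc(g: nx.Graph) -> dict:
    out = {v: 0.0 for v in g.nodes}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += w
    return out


def _deterministic_bfs_tree(g: nx.Graph, root, order: dict):
    """BFS parent array with neighbors visited in ascending label order."""
    parent = {root: None}
    q = deque([root])
    visit_order = [root]
    while q:
        u = q.popleft()
        for w in sorted(g[u], key=lambda x: order[x]):
            if w not in parent:
                parent[w] = u
                q.append(w)
                visit_order.append(w)
    return parent, visit_order


def _bottleneck(g: nx.Graph) -> dict:
    nodes = sorted(g.nodes)
    order = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    for s in nodes:
        parent, visit_order = _deterministic_bfs_tree(g, s, order)
        subtree = {v: 1 for v in parent}
        for v in reversed(visit_order):
            p = parent[v]
            if p is not None:
                subtree[p] += subtree[v]
        for v, size in subtree.items():
            if size > n / 4.0:
                out[v] += 1.0
    return out


def _epc(g: nx.Graph, realizations: int, keep_prob: float, seed: int) -> dict:
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    edges = np.array([(idx[a], idx[b]) for a, b in g.edges], dtype=np.int64)
    rng = np.random.default_rng(seed)
    totals = np.zeros(n)
    for _ in range(realizations):
        if edges.size:
            keep = rng.random(len(edges)) < keep_prob
            kept = edges[keep]
        else:
            kept = np.empty((0, 2), dtype=np.int64)
        adj = coo_matrix(
            (np.ones(len(kept)), (kept[:, 0], kept[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels, minlength=labels.max() + 1)
        totals += sizes[labels]
    return {v: float(totals[idx[v]] / realizations) for v in nodes}


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

def compute_centrality(
    graph: nx.Graph,
    method: str,
    epc_realizations: int = 1000,
    epc_keep_prob: float = 0.5,
    seed: int | None = None,
) -> dict:
    """Score every node of an undirected simple graph by one method."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph must be non-empty")
    if method == "Degree":
        return {v: float(d) for v, d in graph.degree()}
    if method == "Closeness":
        return {v: float(s) for v, s in nx.harmonic_centrality(graph).items()}
    if method == "Betweenness":
        return {
            v: float(s)
            for v, s in nx.betweenness_centrality(graph, normalized=False).items()
        }
    if method == "Stress":
        return _stress(graph)
    if method == "EcCentricity":
        return _eccentricity_scores(graph)
    if method == "Radiality":
        return _radiality(graph)
    if method == "MNC":
        return _mnc(graph)
    if method == "MCC":
        return _mcc(graph)
    if method == "BottleNeck":
        return _bottleneck(graph)
    if method == "EPC":
        if seed is None:
            raise ValueError("EPC requires a seed for its edge-retention draws")
        return _epc(graph, epc_realizations, epc_keep_prob, seed)
    raise ValueError(f"unknown centrality method {method!r}")


def centrality_table(
    graph: nx.Graph,
    epc_realizations: int = 1000,
    epc_keep_prob: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """All ten centrality scores as a nodes x methods table."""
    cols = {
        m: compute_centrality(
            graph, m, epc_realizations=epc_realizations,
            epc_keep_prob=epc_keep_prob, seed=seed,
        )
        for m in CENTRALITY_METHODS
    }
    return pd.DataFrame(cols).loc[sorted(graph.nodes)]


def rank_top_fraction(scores: dict, fraction: float = 0.10) -> set:
    """Top ceil(fraction * n) nodes by score, ties broken by ascending label."""
    if not scores:
        raise ValueError("score table is empty")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    k = math.ceil(fraction * len(scores))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return {v for v, _ in ranked[:k]}


@dataclass
class HubConsensus:
    """Per-method top sets plus their intersection (the consensus hubs)."""

    per_method: dict
    hubs: set
    top_fraction: float

    def summary(self) -> str:
        lines = [
            "Consensus hub detection",
            "=======================",
            f"top fraction per method: {self.top_fraction:.0%}",
        ]
        for m in CENTRALITY_METHODS:
            lines.append(f"{m:<14}{len(self.per_method[m]):>5} nodes")
        lines.append(f"consensus hubs: {len(self.hubs)}")
        lines.append(", ".join(sorted(self.hubs)))
        return "\n".join(lines)


def consensus_hubs(
    graph: nx.Graph,
    fraction: float = 0.10,
    seed: int = 0,
    epc_realizations: int = 1000,
    epc_keep_prob: float = 0.5,
) -> HubConsensus:
    """Intersection of the ten methods' top-fraction node sets."""
    if graph.number_of_nodes() < 10:
        raise ValueError("consensus hub detection needs >= 10 nodes")
    per_method = {}
    for m in CENTRALITY_METHODS:
        scores = compute_centrality(
            graph, m, epc_realizations=epc_realizations,
            epc_keep_prob=epc_keep_prob, seed=seed,
        )
        per_method[m] = rank_top_fraction(scores, fraction)
    hubs = set.intersection(*per_method.values())
    return HubConsensus(per_method=per_method, hubs=hubs, top_fraction=fraction)
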