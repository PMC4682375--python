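"""Molecular Complex Detection (MCODE) for cooperative-module extraction.

From-scratch implementation of the three MCODE stages:

1. *Vertex weighting.* Each vertex is weighted by its core-clustering
   coefficient: the density of the highest k-core of its closed
   neighbourhood, multiplied by that core's index k. Vertices below the
   degree cutoff weigh 0.
2. *Complex prediction.* Seeds are taken in decreasing weight order;
   a breadth-first expansion admits unvisited neighbours whose weight is
   within ``node_score_cutoff`` of the seed weight.
3. *Post-processing.* Complexes without a k-core (default 2-core) are
   discarded; the haircut iteratively strips degree-<2 vertices; the
   optional fluff step adds dense boundary neighbours (fluffed vertices
   may belong to several modules). Modules are scored by
   density x size = 2E/(V-1) and ranked.

Ties (seed choice, ranking) break lexicographically on vertex id so the
output is independent of input vertex order.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .config import McodeParams


@dataclass(frozen=True)
class CooperativeModule:
    """One extracted module: members plus the density x size score."""

    rank: int
    members: frozenset
    n_nodes: int
    n_edges: int
    score: float

    def member_list(self) -> list[str]:
        return sorted(self.members)


def _check_simple(graph: nx.Graph) -> None:
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("MCODE expects a simple undirected graph")
    loops = list(nx.nodes_with_selfloops(graph))
    if loops:
        raise ValueError(f"self-loops are not allowed: {loops[:5]}")


def core_number(graph: nx.Graph) -> dict:
    """Largest k such that each vertex lies in a subgraph of min degree k.

    Iterative peeling: repeatedly remove every vertex of degree < k,
    assigning core number k-1 to vertices removed while peeling to k.
    """
    _check_simple(graph)
    degree = dict(graph.degree())
    remaining = set(graph)
    adj = {v: set(graph[v]) for v in graph}
    core: dict = {}
    k = 0
    while remaining:
        peel = [v for v in remaining if degree[v] <= k]
        while peel:
            v = peel.pop()
            if v not in remaining:
                continue
            core[v] = k
            remaining.discard(v)
            for u in adj[v]:
                if u in remaining:
                    degree[u] -= 1
                    if degree[u] <= k:
                        peel.append(u)
        k += 1
    return core


def _density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def _highest_core_subgraph(graph: nx.Graph):
    """(k_max, induced subgraph on vertices of maximal core number)."""
    core = core_number(graph)
    if not core:
        return 0, graph.subgraph([])
    k_max = max(core.values())
    keep = [v for v, k in core.items() if k == k_max]
    return k_max, graph.subgraph(keep)


def vertex_weight(graph: nx.Graph, v, params: McodeParams | None = None) -> float:
    """Core-clustering-coefficient weight of vertex ``v``."""
    params = params or McodeParams()
    if graph.degree(v) < params.degree_cutoff:
        return 0.0
    closed = graph.subgraph(set(graph[v]) | {v})
    k_max, core_sub = _highest_core_subgraph(closed)
    return k_max * _density(core_sub.number_of_nodes(), core_sub.number_of_edges())


def vertex_weights(graph: nx.Graph, params: McodeParams | None = None) -> dict:
    _check_simple(graph)
    params = params or McodeParams()
    return {v: vertex_weight(graph, v, params) for v in graph}


def find_complexes(
    graph: nx.Graph, params: McodeParams | None = None, weights: dict | None = None
) -> list[frozenset]:
    """Greedy seed expansion over the weighted graph.

    Each complex keeps the admission threshold of its seed:
    weight(u) >= seed_weight * (1 - node_score_cutoff). Visited vertices
    are never re-used; complexes of fewer than 2 vertices are dropped.
    """
    params = params or McodeParams()
    if weights is None:
        weights = vertex_weights(graph, params)
    order = sorted(graph, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    complexes: list[frozenset] = []
    for seed in order:
        if seed in visited:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for v in frontier:
                for u in sorted(graph[v], key=str):
                    if u not in visited and weights[u] >= threshold:
                        visited.add(u)
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        if len(members) >= 2:
            complexes.append(frozenset(members))
    return complexes


def _haircut(graph: nx.Graph, members: set) -> set:
    members = set(members)
    changed = True
    while changed:
        sub = graph.subgraph(members)
        drop = [v for v in members if sub.degree(v) < 2]
        changed = bool(drop)
        members -= set(drop)
    return members


def _fluff(graph: nx.Graph, members: set, cutoff: float) -> set:
    added = set()
    for v in sorted(members, key=str):
        for u in graph[v]:
            if u in members or u in added:
                continue
            closed = graph.subgraph(set(graph[u]) | {u})
            if _density(closed.number_of_nodes(), closed.number_of_edges()) > cutoff:
                added.add(u)
    return members | added


def score_complex(n_nodes: int, n_edges: int) -> float:
    """Density x size cluster score, 2E/(V(V-1)) x V = 2E/(V-1)."""
    if n_nodes < 2:
        raise ValueError("score_complex requires at least 2 nodes")
    return _density(n_nodes, n_edges) * n_nodes


def format_score(score: float) -> str:
    """Score rounded half-up to 3 decimals with trailing zeros trimmed."""
    import decimal

    d = decimal.Decimal(repr(float(score))).quantize(
        decimal.Decimal("0.001"), rounding=decimal.ROUND_HALF_UP
    )
    s = str(d).rstrip("0").rstrip(".")
    return s if s else "0"


def post_process(
    complexes: list[frozenset], graph: nx.Graph, params: McodeParams | None = None
) -> list[CooperativeModule]:
    """Filter by k-core, haircut/fluff, score and rank the complexes."""
    params = params or McodeParams()
    modules = []
    for members in complexes:
        sub = graph.subgraph(members)
        core = core_number(sub)
        if not core or max(core.values()) < params.k_core:
            continue
        kept = set(members)
        if params.haircut:
            kept = _haircut(graph, kept)
        if params.fluff:
            kept = _fluff(graph, kept, params.fluff_cutoff)
        if len(kept) < 2:
            continue
        sub = graph.subgraph(kept)
        n, e = sub.number_of_nodes(), sub.number_of_edges()
        modules.append((frozenset(kept), n, e, score_complex(n, e)))
    modules.sort(key=lambda t: (-t[3], sorted(str(v) for v in t[0])))
    return [
        CooperativeModule(rank=i + 1, members=m, n_nodes=n, n_edges=e, score=s)
        for i, (m, n, e, s) in enumerate(modules)
    ]


def mcode(graph: nx.Graph, params: McodeParams | None = None) -> list[CooperativeModule]:
    """Run the full MCODE pipeline on a simple undirected graph."""
    params = params or McodeParams()
    _check_simple(graph)
    weights = vertex_weights(graph, params)
    complexes = find_complexes(graph, params, weights)
    return post_process(complexes, graph, params)
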