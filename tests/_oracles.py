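"""Independent brute-force oracles for centrality metrics.

Everything here works from a plain adjacency dict via exhaustive
enumeration (all simple paths, all vertex subsets), deliberately avoiding
the implementations (and the library algorithms) under test.  Usable only
for small graphs.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial
from typing import Dict, FrozenSet, List, Set


def adjacency(graph) -> Dict[str, Set[str]]:
    """Adjacency sets from a networkx-like undirected graph."""
    adj = {v: set() for v in graph.nodes}
    for u, v in graph.edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def all_shortest_paths(adj, s, t) -> List[List[str]]:
    """Every shortest s-t path by exhaustive DFS over simple paths."""
    best: List[List[str]] = []
    best_len = [len(adj) + 1]

    def walk(path):
        v = path[-1]
        if v == t:
            if len(path) < best_len[0]:
                best_len[0] = len(path)
                best.clear()
            if len(path) == best_len[0]:
                best.append(list(path))
            return
        if len(path) >= best_len[0]:
            return
        for w in sorted(adj[v]):
            if w not in path:
                path.append(w)
                walk(path)
                path.pop()

    walk([s])
    return best


def betweenness_oracle(adj) -> Dict[str, float]:
    out = {v: 0.0 for v in adj}
    nodes = sorted(adj)
    for s, t in combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out


def stress_oracle(adj) -> Dict[str, float]:
    out = {v: 0.0 for v in adj}
    nodes = sorted(adj)
    for s, t in combinations(nodes, 2):
        for p in all_shortest_paths(adj, s, t):
            for v in p[1:-1]:
                out[v] += 1.0
    return out


def _is_clique(adj, nodes: FrozenSet[str]) -> bool:
    return all(b in adj[a] for a, b in combinations(nodes, 2))


def maximal_cliques_oracle(adj) -> List[FrozenSet[str]]:
    nodes = sorted(adj)
    cliques = [
        frozenset(sub)
        for r in range(1, len(nodes) + 1)
        for sub in combinations(nodes, r)
        if _is_clique(adj, frozenset(sub))
    ]
    return [
        c
        for c in cliques
        if not any(c < other for other in cliques)
    ]


def mcc_oracle(adj) -> Dict[str, float]:
    out = {v: 0.0 for v in adj}
    for clique in maximal_cliques_oracle(adj):
        for v in clique:
            out[v] += factorial(len(clique) - 1)
    return out


def _components(adj, nodes: Set[str]) -> List[Set[str]]:
    remaining = set(nodes)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for w in adj[v] & set(nodes):
                if w not in comp:
                    comp.add(w)
                    frontier.append(w)
        remaining -= comp
        comps.append(comp)
    return comps


def mnc_oracle(adj) -> Dict[str, float]:
    out = {}
    for v in adj:
        nbrs = adj[v]
        comps = _components(adj, nbrs)
        out[v] = float(max((len(c) for c in comps), default=0))
    return out


def dmnc_oracle(adj) -> Dict[str, float]:
    out = {}
    for v in adj:
        nbrs = adj[v]
        comps = _components(adj, nbrs)
        if not comps:
            out[v] = 0.0
            continue
        comp = max(comps, key=lambda c: (len(c), sorted(c)))
        edges = sum(1 for a, b in combinations(sorted(comp), 2) if b in adj[a])
        out[v] = edges / len(comp) ** 1.7
    return out
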