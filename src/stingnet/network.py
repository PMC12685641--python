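"""Species interaction graph and CytoHubba-style node ranking.

The kinetic model is projected onto a directed graph: for each reaction,
every reactant and modifier (source) points at every product (target).
Parallel duplicate edges are collapsed.  All centralities are computed on
the undirected simple view of this graph (self-loops dropped), which is the
convention under which the published radius/diameter/clustering figures are
mutually consistent; the directed graph is preserved for export.

Twelve node-ranking metrics are provided: degree, (harmonic) closeness,
betweenness, bottleneck, clustering coefficient, MNC, DMNC, eccentricity,
EPC, MCC, radiality and stress.  A node's "hub frequency" is the number of
metrics in whose top-k list it appears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .core import ReactionModel

__all__ = [
    "InteractionNetwork",
    "METRICS",
    "model_to_network",
    "topology_summary",
    "centrality",
    "centrality_table",
    "hub_frequency",
]

METRICS = (
    "degree",
    "closeness",
    "betweenness",
    "bottleneck",
    "clustering_coefficient",
    "MNC",
    "DMNC",
    "eccentricity",
    "EPC",
    "MCC",
    "radiality",
    "stress",
)


@dataclass
class InteractionNetwork:
    """Directed species graph with a cached undirected simple view."""

    graph: nx.DiGraph
    name: str = "network"

    @classmethod
    def from_undirected(cls, g: nx.Graph, name: str = "network") -> "InteractionNetwork":
        return cls(graph=g.to_directed(as_view=False), name=name)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Deduplicated directed edge count (self-loops included)."""
        return self.graph.number_of_edges()

    def nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    def undirected(self) -> nx.Graph:
        """Undirected simple view: collapsed direction, no self-loops."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.graph.nodes))
        for u, v in self.graph.edges:
            if u != v:
                g.add_edge(u, v)
        return g

    def to_edgelist(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v} for u, v in sorted(self.graph.edges)]
        return pd.DataFrame(rows, columns=["source", "target"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def from_edgelist(cls, df: pd.DataFrame, name: str = "network") -> "InteractionNetwork":
        g = nx.DiGraph()
        g.add_edges_from(zip(df["source"], df["target"]))
        return cls(graph=g, name=name)


def model_to_network(model: ReactionModel) -> InteractionNetwork:
    """Project a kinetic model onto its species interaction graph."""
    g = nx.DiGraph()
    names = {s.id: s.name for s in model.species}
    for r in model.reactions:
        sources = [sid for sid, _ in r.reactants] + list(r.modifiers)
        targets = [sid for sid, _ in r.products]
        for s in sources:
            for t in targets:
                if s != t:
                    g.add_edge(s, t)
    # deterministic node order: lexicographic id
    h = nx.DiGraph()
    h.add_nodes_from(sorted(g.nodes))
    h.add_edges_from(sorted(g.edges))
    nx.set_node_attributes(h, {n: names.get(n, n) for n in h.nodes}, "name")
    return InteractionNetwork(graph=h, name=model.name)


# ---------------------------------------------------------------------------
# topology summary


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_neighbors: float
    radius: int
    diameter: int
    avg_clustering: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "avg_neighbors": self.avg_neighbors,
            "radius": self.radius,
            "diameter": self.diameter,
            "avg_clustering": self.avg_clustering,
        }


def topology_summary(network: InteractionNetwork) -> TopologySummary:
    """Whole-network statistics on the undirected simple view.

    Radius and diameter are taken over the largest connected component.
    ``avg_degree`` is 2E/N on the simple view; ``avg_neighbors`` is the mean
    neighbor count (identical on a simple graph, reported separately because
    some tools compute it on the multigraph).  The average clustering
    coefficient is the mean local coefficient over all nodes, with nodes of
    degree < 2 contributing 0.
    """
    g = network.undirected()
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    ecc = nx.eccentricity(sub)
    clustering = nx.clustering(g)
    return TopologySummary(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        avg_degree=2.0 * g.number_of_edges() / n,
        avg_neighbors=float(np.mean([g.degree(v) for v in g.nodes])),
        radius=min(ecc.values()),
        diameter=max(ecc.values()),
        avg_clustering=float(np.mean(list(clustering.values()))),
    )


# ---------------------------------------------------------------------------
# centralities


def _per_component(g: nx.Graph) -> Iterable[nx.Graph]:
    for comp in nx.connected_components(g):
        yield g.subgraph(comp)


def _stress(g: nx.Graph) -> Dict[str, float]:
    """Stress centrality: number of shortest paths passing through a node."""
    # Count sigma (number of shortest s->v paths) and distances from every
    # source with BFS, then sum sigma_sv * sigma_vt over pairs (s, t) whose
    # shortest paths run through v.
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    sig = np.zeros((n, n))
    dm = np.full((n, n), np.inf)
    for s in nodes:
        si = index[s]
        sigma = dict.fromkeys(nodes, 0.0)
        dist = dict.fromkeys(nodes, -1)
        sigma[s] = 1.0
        dist[s] = 0
        queue = [s]
        while queue:
            v = queue.pop(0)
            for w in g.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
        for v in nodes:
            if dist[v] >= 0:
                sig[si, index[v]] = sigma[v]
                dm[si, index[v]] = dist[v]
    out = dict.fromkeys(g.nodes, 0.0)
    for v in nodes:
        vi = index[v]
        # pairs (s, t), s != v != t, with d(s,v) + d(v,t) == d(s,t)
        through = (dm[:, vi][:, None] + dm[vi, :][None, :]) == dm
        through[vi, :] = False
        through[:, vi] = False
        np.fill_diagonal(through, False)
        count = (sig[:, vi][:, None] * sig[vi, :][None, :])[through].sum()
        out[v] = count / 2.0  # each unordered pair counted twice
    return out


def _mnc_subgraph(g: nx.Graph, v: str) -> nx.Graph:
    """Largest connected component of the neighborhood subgraph N(v)."""
    nbrs = list(g.neighbors(v))
    if not nbrs:
        return g.subgraph([])
    sub = g.subgraph(nbrs)
    comp = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(c)))
    return sub.subgraph(comp)


def _mcc(g: nx.Graph) -> Dict[str, float]:
    out = dict.fromkeys(g.nodes, 0.0)
    for clique in nx.find_cliques(g):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += w
    return out


def _bottleneck(g: nx.Graph) -> Dict[str, float]:
    """Number of BFS shortest-path trees in which a node roots a subtree
    containing more than n/4 of the tree's nodes.  Trees are built with a
    deterministic BFS (neighbors in sorted order, first-found parent)."""
    out = dict.fromkeys(g.nodes, 0.0)
    for comp in _per_component(g):
        n_comp = comp.number_of_nodes()
        for s in sorted(comp.nodes):
            parent: Dict[str, Optional[str]] = {s: None}
            order = [s]
            queue = [s]
            while queue:
                v = queue.pop(0)
                for w in sorted(comp.neighbors(v)):
                    if w not in parent:
                        parent[w] = v
                        order.append(w)
                        queue.append(w)
            size = dict.fromkeys(order, 1)
            for v in reversed(order):
                p = parent[v]
                if p is not None:
                    size[p] += size[v]
            for v in order:
                if size[v] > n_comp / 4.0:
                    out[v] += 1.0
    return out


def _epc(
    g: nx.Graph, n_realizations: int, keep_probability: float, seed: int
) -> Dict[str, float]:
    """Edge-percolated component: mean size of a node's component over
    random edge-retention realizations."""
    rng = np.random.default_rng(seed)
    edges = sorted(g.edges)
    out = dict.fromkeys(g.nodes, 0.0)
    for _ in range(n_realizations):
        keep = rng.random(len(edges)) < keep_probability
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        h.add_edges_from(e for e, k in zip(edges, keep) if k)
        for comp in nx.connected_components(h):
            size = float(len(comp))
            for v in comp:
                out[v] += size
    return {v: s / n_realizations for v, s in out.items()}


def centrality(
    network: InteractionNetwork,
    metric: str,
    *,
    n_realizations: int = 1000,
    keep_probability: float = 0.5,
    seed: Optional[int] = None,
) -> Dict[str, float]:
    """Compute one of the twelve node-ranking metrics.

    EPC is a randomized metric and requires an explicit ``seed`` so results
    are reproducible.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    g = network.undirected()
    if metric == "degree":
        return {v: float(d) for v, d in g.degree()}
    if metric == "closeness":
        return {v: float(c) for v, c in nx.harmonic_centrality(g).items()}
    if metric == "betweenness":
        return nx.betweenness_centrality(g, normalized=False)
    if metric == "stress":
        return _stress(g)
    if metric == "clustering_coefficient":
        return {v: float(c) for v, c in nx.clustering(g).items()}
    if metric == "eccentricity":
        out = {}
        for comp in _per_component(g):
            ecc = nx.eccentricity(comp)
            for v, e in ecc.items():
                out[v] = 1.0 / e if e > 0 else 0.0
        return out
    if metric == "radiality":
        out = {}
        for comp in _per_component(g):
            n_comp = comp.number_of_nodes()
            if n_comp == 1:
                out[next(iter(comp.nodes))] = 0.0
                continue
            ecc = nx.eccentricity(comp)
            delta = max(ecc.values())
            for v in comp.nodes:
                dist = nx.single_source_shortest_path_length(comp, v)
                out[v] = sum(delta + 1 - d for w, d in dist.items() if w != v) / (
                    n_comp - 1
                )
        return out
    if metric == "MNC":
        return {v: float(_mnc_subgraph(g, v).number_of_nodes()) for v in g.nodes}
    if metric == "DMNC":
        out = {}
        for v in g.nodes:
            sub = _mnc_subgraph(g, v)
            n_sub = sub.number_of_nodes()
            out[v] = sub.number_of_edges() / n_sub**1.7 if n_sub > 0 else 0.0
        return out
    if metric == "MCC":
        return _mcc(g)
    if metric == "bottleneck":
        return _bottleneck(g)
    if metric == "EPC":
        if seed is None:
            raise ValueError("EPC requires an explicit seed for reproducibility")
        return _epc(g, n_realizations, keep_probability, seed)
    raise AssertionError("unreachable")


def centrality_table(
    network: InteractionNetwork,
    *,
    n_realizations: int = 1000,
    keep_probability: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """All twelve metrics, one row per node."""
    data = {
        metric: centrality(
            network,
            metric,
            n_realizations=n_realizations,
            keep_probability=keep_probability,
            seed=seed,
        )
        for metric in METRICS
    }
    df = pd.DataFrame(data, index=network.nodes())
    df.index.name = "node"
    df.attrs["epc_seed"] = seed
    df.attrs["epc_realizations"] = n_realizations
    df.attrs["epc_keep_probability"] = keep_probability
    return df


@dataclass
class HubReport:
    frequency: Dict[str, int]
    k: int
    top_lists: Dict[str, List[str]] = field(default_factory=dict)

    def ranked(self) -> List[Tuple[str, int]]:
        return sorted(self.frequency.items(), key=lambda kv: (-kv[1], kv[0]))

    def max_frequency_nodes(self) -> List[str]:
        best = max(self.frequency.values(), default=0)
        return [v for v, f in self.ranked() if f == best]


def hub_frequency(table: pd.DataFrame, k: int = 20) -> HubReport:
    """Frequency-of-occurrence hub selection.

    For each metric the top-``k`` nodes are taken (ties broken by node id);
    a node's frequency is the number of metrics in whose top-k list it
    appears.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    freq = dict.fromkeys(table.index, 0)
    lists: Dict[str, List[str]] = {}
    for metric in table.columns:
        ranked = sorted(table.index, key=lambda v: (-table.at[v, metric], v))
        top = ranked[:k]
        lists[metric] = top
        for v in top:
            freq[v] += 1
    return HubReport(frequency=freq, k=k, top_lists=lists)
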