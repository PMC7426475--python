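"""Binary-graph measures of integration, segregation, centrality, resilience.

Conventions for degenerate inputs are fixed so that feature matrices stay
rectangular and finite: characteristic path length averages finite
distances only, unreachable pairs contribute 0 to efficiency, and
undefined values (assortativity of a regular graph, within-module z-score
of a constant-degree module, eigenvector centrality off the largest
component) map to a 0 sentinel with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "GlobalMetricSet",
    "CommunityPartition",
    "degree",
    "clustering_coefficient",
    "transitivity",
    "shortest_path_metrics",
    "local_efficiency",
    "betweenness_centrality",
    "eigenvector_centrality",
    "detect_communities",
    "participation_coefficient",
    "within_module_zscore",
    "assortativity",
]


@dataclass(frozen=True)
class GlobalMetricSet:
    """Whole-graph summary measures."""

    characteristic_path_length: float
    global_efficiency: float
    transitivity: float
    assortativity: float


@dataclass(frozen=True)
class CommunityPartition:
    """Node→module assignment plus the modularity it achieves."""

    assignment: tuple[int, ...]
    modularity_q: float

    def module_of(self, node: int) -> int:
        return self.assignment[node]

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment))


def degree(graph) -> np.ndarray:
    g = graph.to_networkx()
    return np.array([g.degree(v) for v in range(graph.n_nodes)], dtype=float)


def clustering_coefficient(graph) -> np.ndarray:
    """Per-node triangle density C_i = 2 t_i / (k_i (k_i - 1)); 0 for k_i < 2."""
    g = graph.to_networkx()
    cc = nx.clustering(g)
    return np.array([cc[v] for v in range(graph.n_nodes)], dtype=float)


def transitivity(graph) -> float:
    """Graph-wide ratio 3·triangles / triads."""
    return float(nx.transitivity(graph.to_networkx()))


def shortest_path_metrics(graph) -> tuple[float, float]:
    """(characteristic path length, global efficiency).

    CPL is the mean shortest-path distance over ordered *reachable* pairs
    (i ≠ j); an edgeless graph has no such pair and yields the 0 sentinel.
    Global efficiency is the mean of 1/d over all ordered pairs, with
    unreachable pairs contributing 0, so it lives in [0, 1] regardless of
    connectedness.
    """
    n = graph.n_nodes
    if n < 2:
        raise ValueError("shortest-path metrics need at least 2 nodes")
    g = graph.to_networkx()
    total_d = 0.0
    total_inv = 0.0
    n_finite = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total_d += d
                total_inv += 1.0 / d
                n_finite += 1
    if n_finite == 0:
        warnings.warn("edgeless graph: characteristic path length set to 0", stacklevel=2)
        return 0.0, 0.0
    cpl = total_d / n_finite
    efficiency = total_inv / (n * (n - 1))
    return cpl, efficiency


def local_efficiency(graph) -> np.ndarray:
    """Global efficiency of each node's neighbour subgraph; 0 for k_i < 2."""
    g = graph.to_networkx()
    out = np.zeros(graph.n_nodes)
    for v in range(graph.n_nodes):
        nbrs = list(g[v])
        if len(nbrs) < 2:
            continue
        sub = g.subgraph(nbrs)
        out[v] = nx.global_efficiency(sub)
    return out


def betweenness_centrality(graph) -> np.ndarray:
    """Unnormalized shortest-path betweenness (endpoints excluded)."""
    g = graph.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[v] for v in range(graph.n_nodes)], dtype=float)


def eigenvector_centrality(graph) -> np.ndarray:
    """Principal adjacency eigenvector on the largest connected component.

    Nonnegative, unit Euclidean norm over the component; nodes outside the
    largest component get 0.  If the largest component has no edges the
    whole vector is the 0 sentinel.
    """
    g = graph.to_networkx()
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    giant = sorted(comps[0])
    out = np.zeros(graph.n_nodes)
    if len(giant) < 2:
        warnings.warn("edgeless graph: eigenvector centrality set to 0", stacklevel=2)
        return out
    a = nx.to_numpy_array(g, nodelist=giant)
    eigval, eigvec = np.linalg.eigh(a)
    v = eigvec[:, -1]
    # Perron-Frobenius: principal eigenvector of a connected component is
    # single-signed; orient it nonnegative
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    v /= np.linalg.norm(v)
    out[giant] = v
    return out


def detect_communities(graph, seed: int = 0) -> CommunityPartition:
    """Louvain modularity maximization with a fixed seed.

    Isolated nodes form singleton modules; an edgeless graph yields all
    singletons with Q = 0.
    """
    g = graph.to_networkx()
    if g.number_of_edges() == 0:
        return CommunityPartition(
            assignment=tuple(range(graph.n_nodes)), modularity_q=0.0
        )
    communities = nx.community.louvain_communities(g, seed=seed)
    assignment = [0] * graph.n_nodes
    for m, nodes in enumerate(communities):
        for v in nodes:
            assignment[v] = m
    q = nx.community.modularity(g, communities)
    return CommunityPartition(assignment=tuple(assignment), modularity_q=float(q))


def participation_coefficient(graph, partition: CommunityPartition) -> np.ndarray:
    """P_i = 1 - sum_s (k_is / k_i)^2; 0 for isolated nodes."""
    if len(partition.assignment) != graph.n_nodes:
        raise ValueError("partition does not cover all nodes")
    g = graph.to_networkx()
    modules = np.asarray(partition.assignment)
    out = np.zeros(graph.n_nodes)
    for v in range(graph.n_nodes):
        nbrs = list(g[v])
        k = len(nbrs)
        if k == 0:
            continue
        counts = np.bincount(modules[nbrs])
        out[v] = 1.0 - float(np.sum((counts / k) ** 2))
    return out


def within_module_zscore(graph, partition: CommunityPartition) -> np.ndarray:
    """Within-module degree standardized against the module's distribution.

    Uses the population SD (divide by module size); modules with zero
    degree spread get the 0 sentinel.
    """
    if len(partition.assignment) != graph.n_nodes:
        raise ValueError("partition does not cover all nodes")
    g = graph.to_networkx()
    modules = np.asarray(partition.assignment)
    within_deg = np.zeros(graph.n_nodes)
    for v in range(graph.n_nodes):
        within_deg[v] = sum(1 for u in g[v] if modules[u] == modules[v])
    out = np.zeros(graph.n_nodes)
    for m in np.unique(modules):
        idx = np.flatnonzero(modules == m)
        mu = within_deg[idx].mean()
        sd = within_deg[idx].std()  # population convention
        if sd > 0:
            out[idx] = (within_deg[idx] - mu) / sd
    return out


def assortativity(graph) -> float:
    """Degree assortativity: Pearson correlation of degrees across the 2E
    ordered edge-endpoint pairs.  Regular graphs (zero endpoint-degree
    variance) get the 0 sentinel with a warning."""
    g = graph.to_networkx()
    if g.number_of_edges() == 0:
        raise ValueError("assortativity needs at least one edge")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.degree_assortativity_coefficient(g)
    if not np.isfinite(r):
        warnings.warn("degenerate degree distribution: assortativity set to 0", stacklevel=2)
        return 0.0
    return float(r)
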