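"""Interaction-network construction and analysis.

Builds an undirected network from retained dimer pairs (self-pairs become
homodimer node flags, not edges), computes PageRank centrality by power
iteration and Walktrap communities (Pons & Latapy random-walk distances,
walk length 8, Ward-style agglomeration, modularity-maximal cut), and
refines networks by expression tables.

networkx supplies only the graph container; both algorithms are
implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_network",
    "pagerank",
    "walktrap",
    "CommunityPartition",
    "filter_by_expression",
    "network_stats",
    "modularity",
]


def build_network(
    pairs: Sequence[Tuple[str, str]],
    group_map: Optional[Mapping[str, str]] = None,
) -> nx.Graph:
    """Undirected network from retained pairs.

    One node per protein appearing in any retained pair; one edge per
    retained heterodimer (duplicates collapse); retained self-pairs set the
    node's ``homodimer`` attribute instead of adding a self-loop.  Nodes
    missing from ``group_map`` are labeled "unknown".
    """
    g = nx.Graph()
    for a, b in pairs:
        for node in sorted({a, b}):
            if node not in g:
                group = (group_map or {}).get(node, "unknown")
                g.add_node(node, group=group, homodimer=False)
        if a == b:
            g.nodes[a]["homodimer"] = True
        else:
            g.add_edge(*sorted((a, b)))
    return g


def pagerank(
    g: nx.Graph, damping: float = 0.85, tol: float = 1e-9, max_iter: int = 1000
) -> Dict[str, float]:
    """PageRank by power iteration on the undirected graph.

    Each undirected edge acts as two directed edges; dangling (isolated)
    nodes redistribute uniformly; convergence when the L1 change drops
    below ``tol``.  Scores sum to 1.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("graph has no nodes")
    index = {v: i for i, v in enumerate(nodes)}
    deg = np.array([g.degree(v) for v in nodes], dtype=float)
    x = np.full(n, 1.0 / n)
    neighbors = [[index[u] for u in g.neighbors(v)] for v in nodes]
    for iteration in range(max_iter):
        new = np.full(n, (1.0 - damping) / n)
        dangling_mass = x[deg == 0].sum()
        new += damping * dangling_mass / n
        for i, nbrs in enumerate(neighbors):
            if deg[i] > 0:
                share = damping * x[i] / deg[i]
                for j in nbrs:
                    new[j] += share
        if np.abs(new - x).sum() < tol:
            return {v: float(new[index[v]]) for v in nodes}
        x = new
    raise RuntimeError(f"PageRank failed to converge in {max_iter} iterations")


def modularity(g: nx.Graph, communities: Mapping[str, int]) -> float:
    """Newman modularity Q = sum_c (e_c/m - (d_c/2m)^2) of a partition."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    e = {}  # intra-community edge count
    d = {}  # community degree sum
    for v in g.nodes:
        d[communities[v]] = d.get(communities[v], 0) + g.degree(v)
    for u, v in g.edges:
        if communities[u] == communities[v]:
            e[communities[u]] = e.get(communities[u], 0) + 1
    return sum(e.get(c, 0) / m - (dc / (2.0 * m)) ** 2 for c, dc in d.items())


@dataclass
class CommunityPartition:
    """Result of community detection: labels, merge history, modularity."""

    membership: Dict[str, int]
    merge_history: List[Tuple[int, int, float]] = field(default_factory=list)
    modularity: float = 0.0

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> List[Tuple[str, ...]]:
        groups: Dict[int, List[str]] = {}
        for v, c in self.membership.items():
            groups.setdefault(c, []).append(v)
        return [tuple(sorted(g)) for _, g in sorted(groups.items())]


def _walktrap_component(g: nx.Graph, nodes: List[str], walk_length: int):
    """Pons-Latapy agglomeration on one connected component.

    Returns (list of partitions along the merge path as lists of frozensets,
    merge history).  The first partition is all-singletons.
    """
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v in g.subgraph(nodes).edges:
        A[index[u], index[v]] = A[index[v], index[u]] = 1.0
    deg = A.sum(axis=1)
    deg[deg == 0] = 1.0  # isolated node inside a "component" of size 1
    P = A / deg[:, None]
    Pt = np.linalg.matrix_power(P, walk_length)  # row i: t-step distribution from i

    inv_sqrt_d = 1.0 / np.sqrt(deg)

    # community state: member sets, size, mean walk distribution
    comms: Dict[int, Dict] = {
        i: {"members": frozenset([nodes[i]]), "size": 1, "dist": Pt[i].copy()} for i in range(n)
    }
    adjacency: Dict[int, set] = {i: set() for i in range(n)}
    for u, v in g.subgraph(nodes).edges:
        if index[u] != index[v]:
            adjacency[index[u]].add(index[v])
            adjacency[index[v]].add(index[u])

    def delta_sigma(c1: int, c2: int) -> float:
        a, b = comms[c1], comms[c2]
        r2 = float(np.sum(((a["dist"] - b["dist"]) * inv_sqrt_d) ** 2))
        return (a["size"] * b["size"]) / (a["size"] + b["size"]) / n * r2

    partitions = [[c["members"] for c in comms.values()]]
    history: List[Tuple[int, int, float]] = []
    next_id = n
    while len(comms) > 1:
        best = None
        for c1 in sorted(comms):
            for c2 in sorted(adjacency[c1]):
                if c2 <= c1:
                    continue
                ds = delta_sigma(c1, c2)
                if best is None or ds < best[0] - 1e-15:
                    best = (ds, c1, c2)
        if best is None:
            break  # no adjacent communities left (cannot happen on a connected comp)
        ds, c1, c2 = best
        a, b = comms.pop(c1), comms.pop(c2)
        size = a["size"] + b["size"]
        merged = {
            "members": a["members"] | b["members"],
            "size": size,
            "dist": (a["size"] * a["dist"] + b["size"] * b["dist"]) / size,
        }
        comms[next_id] = merged
        nbrs = (adjacency.pop(c1) | adjacency.pop(c2)) - {c1, c2}
        adjacency[next_id] = set()
        for x in nbrs:
            adjacency[x].discard(c1)
            adjacency[x].discard(c2)
            adjacency[x].add(next_id)
            adjacency[next_id].add(x)
        history.append((c1, c2, ds))
        partitions.append([c["members"] for c in comms.values()])
        next_id += 1
    return partitions, history


def walktrap(g: nx.Graph, walk_length: int = 8) -> CommunityPartition:
    """Walktrap communities: random-walk distances, Ward agglomeration,
    modularity-maximal cut (ties resolved toward fewer communities).

    Disconnected components are processed independently; isolated nodes
    form their own communities.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort()

    per_comp_paths = []
    full_history: List[Tuple[int, int, float]] = []
    for comp in components:
        if len(comp) == 1:
            per_comp_paths.append([[frozenset(comp)]])
            continue
        partitions, history = _walktrap_component(g, comp, walk_length)
        per_comp_paths.append(partitions)
        full_history.extend(history)

    # choose, per component, the cut maximizing global modularity; since
    # modularity is additive over components we optimize each independently.
    best_partition: List[frozenset] = []
    for comp, paths in zip(components, per_comp_paths):
        best_q, best_cut = -math.inf, None
        for cut in paths:
            membership = {}
            for ci, members in enumerate(cut):
                for v in members:
                    membership[v] = ci
            # modularity of the component's own subgraph; components are
            # optimized independently
            q = modularity(g.subgraph(comp), membership)
            # prefer fewer communities on ties (later cuts have fewer)
            if q >= best_q - 1e-12:
                best_q, best_cut = max(best_q, q), cut
        best_partition.extend(best_cut)

    membership = {}
    for ci, members in enumerate(best_partition):
        for v in members:
            membership[v] = ci
    return CommunityPartition(
        membership=membership,
        merge_history=full_history,
        modularity=modularity(g, membership),
    )


def filter_by_expression(
    g: nx.Graph,
    expression: pd.DataFrame,
    condition: str,
    threshold: float = 0.0,
) -> nx.Graph:
    """Induced subnetwork on nodes expressed above ``threshold``.

    ``expression`` needs an ``id`` column and one column per condition.
    Nodes absent from the table are dropped (with their edges); homodimer
    flags travel with their node.
    """
    if condition not in expression.columns:
        raise ValueError(f"no condition column {condition!r} in expression table")
    values = dict(zip(expression["id"], expression[condition]))
    keep = [v for v in g.nodes if v in values and values[v] > threshold]
    return g.subgraph(keep).copy()


def network_stats(
    g: nx.Graph,
    partition: Optional[CommunityPartition] = None,
    scores: Optional[Mapping[str, float]] = None,
    n_tested: Optional[int] = None,
) -> Dict:
    """Summary statistics of a network.

    density = 2E/(n(n-1)); the homodimer share is reported both exactly and
    rounded to an integer percent of ``n_tested`` (default: node count).
    """
    n = g.number_of_nodes()
    e = g.number_of_edges()
    homodimers = [v for v, d in g.nodes(data=True) if d.get("homodimer")]
    tested = n_tested if n_tested is not None else n
    per_group: Dict[str, List[int]] = {}
    for v, d in g.nodes(data=True):
        per_group.setdefault(d.get("group", "unknown"), []).append(g.degree(v))
    stats = {
        "n_nodes": n,
        "n_edges": e,
        "density": (2.0 * e / (n * (n - 1))) if n > 1 else 0.0,
        "homodimer_count": len(homodimers),
        "homodimer_nodes": sorted(homodimers),
        "homodimer_share_exact": (100.0 * len(homodimers) / tested) if tested else 0.0,
        "homodimer_share_percent": int(math.floor(100.0 * len(homodimers) / tested + 0.5))
        if tested
        else 0,
        "mean_degree_per_group": {k: float(np.mean(v)) for k, v in sorted(per_group.items())},
    }
    if partition is not None:
        stats["n_communities"] = partition.n_communities
        stats["community_sizes"] = sorted(
            (len(c) for c in partition.communities()), reverse=True
        )
        stats["modularity"] = partition.modularity
    if scores is not None:
        stats["pagerank_top"] = sorted(scores, key=scores.get, reverse=True)[:5]
    return stats


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def edges_to_frame(g: nx.Graph) -> pd.DataFrame:
    return pd.DataFrame(sorted(g.edges), columns=["id1", "id2"])
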