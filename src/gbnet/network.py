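"""Residue-interaction networks: Calpha contact graphs, shortest
communication paths and betweenness.

A residue is a node (its Calpha atom), and an edge joins two residues
whose Calpha-Calpha distance is strictly below the cutoff (default 7 A).
Edges store the distance, but path lengths are measured in HOPS on the
unweighted graph: the shortest path distance between two residues is the
minimum number of nodes traversed, and a node's betweenness is the raw
COUNT of shortest paths passing through it, summed over all unordered
endpoint pairs that exclude the node.  This raw-count convention is
deliberately not Brandes' fractional betweenness; a normalized variant is
available behind a flag.  All-pairs hop distances come from
Floyd-Warshall; a distance-weighted path mode is available behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable

import networkx as nx
import numpy as np

from .io import MolecularStructure

__all__ = [
    "ContactNetwork",
    "PathResult",
    "BetweennessReport",
    "build_contact_network",
    "network_from_edges",
    "floyd_warshall",
    "shortest_path",
    "betweenness",
]

_MAX_ENUMERATED_PATHS = 10_000


@dataclass
class ContactNetwork:
    """Residue contact graph; nodes are residue ids, edges carry distance."""

    graph: nx.Graph
    cutoff_used: float

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def to_edge_list_tsv(self) -> str:
        lines = ["res_i\tres_j\tdistance_A"]
        for u, v in self.edges:
            d = self.graph.edges[u, v].get("distance", float("nan"))
            lines.append(f"{u}\t{v}\t{d:.3f}")
        return "\n".join(lines) + "\n"


@dataclass
class PathResult:
    """One source-target communication path on the hop graph.

    ``node_sequence`` is the canonical (lexicographically smallest)
    shortest path including both endpoints; ``n_intermediate`` counts the
    residues strictly between them.  ``all_shortest_paths`` enumerates
    every co-optimal path when their count is <= 10^4, else is None.
    ``node_sequence`` is None for disconnected endpoints (a no-path
    result, not an error).
    """

    endpoints: tuple
    node_sequence: list | None
    n_intermediate: int | None
    all_shortest_paths: list[list] | None

    @property
    def connected(self) -> bool:
        return self.node_sequence is not None

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.endpoints[0],
                "target": self.endpoints[1],
                "path": self.node_sequence,
                "n_intermediate": self.n_intermediate,
                "n_shortest_paths": (
                    len(self.all_shortest_paths)
                    if self.all_shortest_paths is not None
                    else None
                ),
                "all_shortest_paths": self.all_shortest_paths,
            },
            indent=2,
        )


@dataclass
class BetweennessReport:
    """Residue id -> betweenness (raw shortest-path counts by default)."""

    values: dict
    normalized: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "normalized": self.normalized,
                "betweenness": {str(k): v for k, v in sorted(self.values.items())},
            },
            indent=2,
        )


def build_contact_network(
    structure: MolecularStructure, cutoff: float = 7.0
) -> ContactNetwork:
    """Calpha contact network with edges for pairs strictly below ``cutoff``.

    Every residue must have exactly one Calpha atom; residues lacking one
    raise a ValueError naming them.  Node ids are residue_ids when unique
    across chains, else ``(chain, residue_id)`` tuples.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca: dict[tuple[str, int], np.ndarray] = {}
    for key, idx in structure.residue_index.items():
        cas = [i for i in idx if structure.atoms[i].name == "CA"]
        if len(cas) != 1:
            raise ValueError(
                f"residue {key[0]}:{key[1]} has {len(cas)} CA atoms (need exactly 1)"
            )
        ca[key] = structure.atoms[cas[0]].position
    rids = [k[1] for k in ca]
    use_plain = len(set(rids)) == len(rids)
    labels = {k: (k[1] if use_plain else k) for k in ca}
    g = nx.Graph()
    g.add_nodes_from(labels.values())
    keys = list(ca)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            dist = float(np.linalg.norm(ca[keys[a]] - ca[keys[b]]))
            if dist < cutoff:
                g.add_edge(labels[keys[a]], labels[keys[b]], distance=dist)
    return ContactNetwork(graph=g, cutoff_used=cutoff)


def network_from_edges(
    edges: Iterable[tuple],
    cutoff: float = float("nan"),
    nodes: Iterable | None = None,
) -> ContactNetwork:
    """Build a network from plain ``(u, v[, distance])`` tuples (for
    graph-only testing and edge-list import); ``nodes`` may add isolated
    nodes."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 3:
            g.add_edge(e[0], e[1], distance=float(e[2]))
        else:
            g.add_edge(e[0], e[1])
    return ContactNetwork(graph=g, cutoff_used=cutoff)


def floyd_warshall(network: ContactNetwork, weighted: bool = False) -> tuple[list, np.ndarray]:
    """All-pairs shortest distances by Floyd-Warshall.

    Unweighted (hop) distances by default; ``weighted=True`` uses the
    stored Calpha-Calpha distances.  Returns (node order, distance matrix)
    with inf for disconnected pairs.
    """
    nodes = sorted(network.graph.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, data in network.graph.edges(data=True):
        w = data.get("distance", 1.0) if weighted else 1.0
        i, j = pos[u], pos[v]
        dist[i, j] = dist[j, i] = min(dist[i, j], w)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    return nodes, dist


def _shortest_path_dag(
    g: nx.Graph, dist_s: dict, dist_t: dict, total: int
) -> dict:
    """Successors along shortest s->t paths: v -> sorted viable neighbors."""
    succ: dict = {}
    for v, dv in dist_s.items():
        if v not in dist_t or dv + dist_t[v] != total:
            continue
        succ[v] = sorted(
            u
            for u in g.neighbors(v)
            if u in dist_s
            and u in dist_t
            and dist_s[u] == dv + 1
            and dist_s[u] + dist_t[u] == total
        )
    return succ


def shortest_path(network: ContactNetwork, source, target) -> PathResult:
    """Shortest communication path between two residues on the hop graph.

    Hop distances come from Floyd-Warshall; the canonical reported path is
    the lexicographically smallest residue-id sequence among co-optimal
    paths, and all co-optimal paths are enumerated when their count is
    <= 10^4 (else ``all_shortest_paths`` is None).  Disconnected endpoints
    yield a no-path result.
    """
    g = network.graph
    for v in (source, target):
        if v not in g:
            raise ValueError(f"residue {v!r} not in network")
    nodes, dist = floyd_warshall(network)
    pos = {v: i for i, v in enumerate(nodes)}
    total = dist[pos[source], pos[target]]
    if not np.isfinite(total):
        return PathResult((source, target), None, None, None)
    total = int(total)
    dist_s = {v: int(dist[pos[source], pos[v]]) for v in nodes
              if np.isfinite(dist[pos[source], pos[v]])}
    dist_t = {v: int(dist[pos[v], pos[target]]) for v in nodes
              if np.isfinite(dist[pos[v], pos[target]])}
    succ = _shortest_path_dag(g, dist_s, dist_t, total)

    # canonical path: greedy smallest next node on the co-optimal DAG
    path = [source]
    while path[-1] != target:
        path.append(succ[path[-1]][0])

    # count paths through the DAG; enumerate if few enough
    count: dict = {target: 1}

    def n_paths(v) -> int:
        if v not in count:
            count[v] = sum(n_paths(u) for u in succ[v])
        return count[v]

    total_paths = n_paths(source)
    all_paths: list[list] | None = None
    if total_paths <= _MAX_ENUMERATED_PATHS:
        all_paths = []
        stack = [[source]]
        while stack:
            p = stack.pop()
            if p[-1] == target:
                all_paths.append(p)
                continue
            for u in reversed(succ[p[-1]]):
                stack.append(p + [u])
        all_paths.sort()
    return PathResult((source, target), path, len(path) - 2, all_paths)


def betweenness(network: ContactNetwork, normalized: bool = False) -> BetweennessReport:
    """Betweenness of every node as raw shortest-path counts.

    For node v, sum over unordered pairs (s, t) with s != v != t of the
    number of shortest s-t paths passing through v:
    sigma_st(v) = sigma_sv * sigma_vt when d(s,v) + d(v,t) = d(s,t).
    ``normalized=True`` divides each pair's count by sigma_st (the common
    fractional convention).
    """
    g = network.graph
    nodes = sorted(g.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        raise ValueError("network is empty")
    _, dist = floyd_warshall(network)

    # sigma[i, j]: number of shortest i-j paths (BFS accumulation per source)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = pos[s]
        sigma[si, si] = 1.0
        order = sorted(
            (v for v in nodes if np.isfinite(dist[si, pos[v]])),
            key=lambda v: dist[si, pos[v]],
        )
        for v in order:
            vi = pos[v]
            if v == s:
                continue
            sigma[si, vi] = sum(
                sigma[si, pos[u]]
                for u in g.neighbors(v)
                if np.isfinite(dist[si, pos[u]])
                and dist[si, pos[u]] == dist[si, vi] - 1
            )

    values = {v: 0.0 for v in nodes}
    for a in range(n):
        for b in range(a + 1, n):
            if not np.isfinite(dist[a, b]) or sigma[a, b] == 0:
                continue
            for vi in range(n):
                if vi == a or vi == b:
                    continue
                if dist[a, vi] + dist[vi, b] == dist[a, b]:
                    through = sigma[a, vi] * sigma[vi, b]
                    if normalized:
                        through /= sigma[a, b]
                    values[nodes[vi]] += through
    return BetweennessReport(values=values, normalized=normalized)
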