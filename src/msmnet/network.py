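"""GC-weighted dynamic residue networks: communities and allosteric paths.

Nodes are residues anchored at their C-alpha atom; an edge is drawn between
two residues whose atoms stay within a distance cutoff (4.5 Angstrom by
default) for at least a persistence fraction (75% by default) of the frames.
Edges are weighted by the information-transfer distance

    d_ij = -ln GC_ij,

so strongly correlated contacts are short.  On this graph we compute weighted
edge betweenness (Brandes), Girvan-Newman divisive communities with the
partition of maximal weighted modularity, inter-community flow, and optimal /
suboptimal source-to-sink paths (Floyd-Warshall with lexicographic tie-breaks;
bounded depth-first enumeration for the suboptimal set).

All tie-breaks are lexicographic, so partitions and paths are reproducible.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gccm import CorrelationMatrix
from .trajectory_io import Topology, Trajectory

__all__ = [
    "NetworkParams",
    "DynamicNetwork",
    "CommunityPartition",
    "PathSet",
    "build_network",
    "edge_betweenness",
    "girvan_newman",
    "weighted_modularity",
    "intercommunity_flow",
    "shortest_path",
    "suboptimal_paths",
    "default_endpoints",
]


@dataclass
class NetworkParams:
    cutoff: float = 4.5  # Angstrom
    persistence: float = 0.75
    neighbor_exclusion: int = 1
    contact_mode: str = "heavy"  # or "calpha"
    gc_floor: float = 1e-6
    log_base: float = math.e


@dataclass
class DynamicNetwork:
    """Residue graph: adjacency dictionaries with per-edge persistence, GC and
    weight ``d_ij = -log GC_ij``."""

    n_nodes: int
    edges: dict  # (i, j) i<j -> dict(persistence, gc, weight)
    params: NetworkParams = field(default_factory=NetworkParams)
    node_tags: list[str] | None = None
    dropped_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        adj: dict[int, dict[int, float]] = {i: {} for i in range(self.n_nodes)}
        for (i, j), attrs in self.edges.items():
            if i == j:
                raise ValueError("self-edges are not allowed")
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"bad edge ({i}, {j})")
            w = attrs["weight"]
            if not (np.isfinite(w) and w >= 0):
                raise ValueError(f"edge ({i}, {j}) has invalid weight {w}")
            adj[i][j] = w
            adj[j][i] = w
        self._adj = adj

    @classmethod
    def from_edges(cls, n_nodes, edges, params=None, node_tags=None):
        """Edges as (i, j, persistence, gc) tuples; weight = -log_base(gc)."""
        params = params or NetworkParams()
        base = math.log(params.log_base)
        table = {}
        for i, j, pers, gc in edges:
            i, j = (i, j) if i < j else (j, i)
            table[(i, j)] = {
                "persistence": float(pers),
                "gc": float(gc),
                "weight": -math.log(gc) / base,
            }
        return cls(n_nodes=n_nodes, edges=table, params=params, node_tags=node_tags)

    def neighbors(self, i: int) -> dict[int, float]:
        return self._adj[i]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_weight(self, i: int, j: int) -> float:
        return self._adj[i][j]

    def subgraph_without(self, removed: set) -> "DynamicNetwork":
        kept = {e: a for e, a in self.edges.items() if e not in removed}
        return DynamicNetwork(self.n_nodes, kept, self.params, self.node_tags)

    def components(self) -> list[list[int]]:
        seen = [False] * self.n_nodes
        comps = []
        for start in range(self.n_nodes):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in self._adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            comps.append(sorted(comp))
        return comps

    def is_connected(self) -> bool:
        return len(self.components()) == 1

    def total_gc(self) -> float:
        return sum(a["gc"] for a in self.edges.values())

    def to_edge_dataframe(self, partition: "CommunityPartition | None" = None) -> pd.DataFrame:
        rows = []
        for (i, j), a in sorted(self.edges.items()):
            row = {"i": i, "j": j, "persistence": a["persistence"], "gc": a["gc"],
                   "weight": a["weight"]}
            if partition is not None:
                row["community_i"] = partition.labels[i]
                row["community_j"] = partition.labels[j]
            rows.append(row)
        return pd.DataFrame(rows)


def build_network(
    traj: Trajectory,
    corr: CorrelationMatrix,
    cutoff: float = 4.5,
    persistence: float = 0.75,
    neighbor_exclusion: int = 1,
    contact_mode: str = "heavy",
    gc_floor: float = 1e-6,
) -> DynamicNetwork:
    """Persistence-filtered contact network weighted by -ln GC.

    Contact persistence of a residue pair is the fraction of frames in which
    the minimum inter-residue atom distance (heavy-atom mode) or the
    C-alpha - C-alpha distance (``contact_mode='calpha'``) is within the
    cutoff.  Edges require persistence >= threshold, sequence separation
    ``|i - j| > neighbor_exclusion`` within a chain, and GC above
    ``gc_floor`` (pairs below the floor are dropped and recorded).
    """
    from scipy.spatial import cKDTree

    top = traj.topology
    n = top.n_residues
    if corr.n_residues != n:
        raise ValueError(
            f"correlation matrix size {corr.n_residues} does not match the "
            f"{n}-residue topology"
        )
    counts: dict[tuple[int, int], int] = {}
    if contact_mode == "calpha":
        coords = traj.calpha_xyz()
        atom_res = np.arange(n)
    elif contact_mode == "heavy":
        heavy = np.array(
            [a for a in range(top.n_atoms) if not top.atom_names[a].startswith("H")],
            dtype=np.intp,
        )
        coords = traj.xyz[:, heavy, :]
        atom_res = top.atom_residue[heavy]
    else:
        raise ValueError(f"unknown contact_mode {contact_mode!r}")
    for t in range(traj.n_frames):
        tree = cKDTree(coords[t])
        seen = set()
        for a, b in tree.query_pairs(cutoff):
            ri, rj = int(atom_res[a]), int(atom_res[b])
            if ri == rj:
                continue
            key = (ri, rj) if ri < rj else (rj, ri)
            seen.add(key)
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    params = NetworkParams(cutoff=cutoff, persistence=persistence,
                           neighbor_exclusion=neighbor_exclusion,
                           contact_mode=contact_mode, gc_floor=gc_floor)
    edges = []
    dropped = []
    for (i, j), c in counts.items():
        pers = c / traj.n_frames
        if pers < persistence:
            continue
        same_chain = top.residues[i].chain == top.residues[j].chain
        if same_chain and abs(i - j) <= neighbor_exclusion:
            continue
        gc = corr.values[i, j]
        if not np.isfinite(gc) or gc <= gc_floor:
            dropped.append((i, j))
            continue
        edges.append((i, j, pers, min(gc, 1.0)))
    tags = [r.chain for r in top.residues]
    net = DynamicNetwork.from_edges(n, edges, params=params, node_tags=tags)
    net.dropped_pairs = dropped
    return net


# ---------------------------------------------------------------------------
# weighted edge betweenness (Brandes) and Girvan-Newman


def _brandes_edge_betweenness(net: DynamicNetwork, nodes: Sequence[int] | None = None):
    """Weighted edge betweenness with equal fractional credit to tied
    shortest paths (Brandes' algorithm, Dijkstra variant)."""
    if nodes is None:
        nodes = range(net.n_nodes)
    bet = {e: 0.0 for e in net.edges}
    for s in nodes:
        dist = {s: 0.0}
        sigma = {s: 1.0}
        preds: dict[int, list[int]] = {s: []}
        done: list[int] = []
        heap = [(0.0, s)]
        finished = set()
        while heap:
            d, u = heapq.heappop(heap)
            if u in finished:
                continue
            finished.add(u)
            done.append(u)
            for v, w in net.neighbors(u).items():
                nd = d + w
                old = dist.get(v)
                if old is None or nd < old - 1e-13:
                    dist[v] = nd
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (nd, v))
                elif abs(nd - old) <= 1e-13:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = {u: 0.0 for u in done}
        for u in reversed(done):
            for p in preds[u]:
                credit = sigma[p] / sigma[u] * (1.0 + delta[u])
                key = (p, u) if p < u else (u, p)
                bet[key] += credit
                delta[p] += credit
    # each undirected pair counted from both endpoints
    return {e: b / 2.0 for e, b in bet.items()}


def edge_betweenness(net: DynamicNetwork) -> dict:
    """Per-edge weighted betweenness over all node pairs (per component)."""
    return _brandes_edge_betweenness(net)


def weighted_modularity(net: DynamicNetwork, labels: Sequence[int]) -> float:
    """Newman weighted modularity Q with GC as edge strength."""
    two_m = 2.0 * net.total_gc()
    if two_m == 0:
        return 0.0
    strength = np.zeros(net.n_nodes)
    for (i, j), a in net.edges.items():
        strength[i] += a["gc"]
        strength[j] += a["gc"]
    q = 0.0
    for (i, j), a in net.edges.items():
        if labels[i] == labels[j]:
            q += 2.0 * a["gc"] / two_m
    for c in set(labels):
        s = strength[[k for k in range(net.n_nodes) if labels[k] == c]].sum()
        q -= (s / two_m) ** 2
    return float(q)


@dataclass
class CommunityPartition:
    """Node -> community id, the modularity of the partition, and the full
    divisive dendrogram (list of partitions from coarse to singletons)."""

    labels: np.ndarray
    modularity: float
    dendrogram: list = field(default_factory=list, repr=False)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.tolist()))

    def community_sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.tolist():
            out[c] = out.get(c, 0) + 1
        return out


def _labels_from_components(comps: list[list[int]], n: int) -> np.ndarray:
    labels = np.empty(n, dtype=np.intp)
    for c, comp in enumerate(sorted(comps, key=lambda x: x[0])):
        labels[comp] = c
    return labels


def girvan_newman(net: DynamicNetwork) -> CommunityPartition:
    """Divisive community detection by iterated removal of the highest-
    betweenness edge (ties -> lexicographically smallest edge), recomputing
    betweenness after every removal, down to singleton communities; the
    returned partition is the sweep level of maximal weighted modularity
    (GC as edge strength), with the full dendrogram retained."""
    if net.n_nodes < 2:
        raise ValueError("need at least two nodes")
    if net.n_edges == 0:
        labels = np.arange(net.n_nodes, dtype=np.intp)
        return CommunityPartition(labels=labels, modularity=0.0,
                                  dendrogram=[labels.copy()])
    work = DynamicNetwork(net.n_nodes, dict(net.edges), net.params, net.node_tags)
    dendrogram = []
    best_labels = None
    best_q = -np.inf
    current = _labels_from_components(work.components(), net.n_nodes)
    dendrogram.append(current.copy())
    q = weighted_modularity(net, current)
    best_labels, best_q = current.copy(), q
    bet = _brandes_edge_betweenness(work)
    while work.n_edges:
        top = max(bet.values())
        target = min(e for e, b in bet.items() if b >= top - 1e-12)
        remaining = {e: a for e, a in work.edges.items() if e != target}
        work = DynamicNetwork(net.n_nodes, remaining, net.params, net.node_tags)
        labels = _labels_from_components(work.components(), net.n_nodes)
        if not np.array_equal(labels, current):
            current = labels
            dendrogram.append(current.copy())
            q = weighted_modularity(net, current)
            if q > best_q + 1e-12:
                best_labels, best_q = current.copy(), q
        if work.n_edges:
            bet = _brandes_edge_betweenness(work)
    return CommunityPartition(labels=best_labels, modularity=best_q,
                              dendrogram=dendrogram)


def _component_of(net: DynamicNetwork, start: int) -> list[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in net.neighbors(u):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return sorted(seen)


def intercommunity_flow(net: DynamicNetwork, partition: CommunityPartition) -> pd.DataFrame:
    """Boundary-edge count and summed boundary-edge betweenness per community
    pair, plus community sizes for proportional rendering."""
    bet = edge_betweenness(net)
    rows: dict[tuple[int, int], list[float]] = {}
    for (i, j), b in bet.items():
        ci, cj = int(partition.labels[i]), int(partition.labels[j])
        if ci == cj:
            continue
        key = (ci, cj) if ci < cj else (cj, ci)
        entry = rows.setdefault(key, [0, 0.0])
        entry[0] += 1
        entry[1] += b
    sizes = partition.community_sizes()
    data = [
        {"community_a": a, "community_b": b, "n_edges": int(cnt),
         "betweenness": flow, "size_a": sizes[a], "size_b": sizes[b]}
        for (a, b), (cnt, flow) in sorted(rows.items())
    ]
    return pd.DataFrame(
        data, columns=["community_a", "community_b", "n_edges", "betweenness",
                       "size_a", "size_b"]
    )


# ---------------------------------------------------------------------------
# shortest and suboptimal paths


def _floyd_warshall(net: DynamicNetwork) -> np.ndarray:
    n = net.n_nodes
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for (i, j), a in net.edges.items():
        w = a["weight"]
        if w < dist[i, j]:
            dist[i, j] = dist[j, i] = w
    for k in range(n):
        dk = dist[k]
        np.minimum(dist, dist[:, k : k + 1] + dk[None, :], out=dist)
    return dist


@dataclass
class PathSet:
    """Optimal and suboptimal simple paths between a source and sink."""

    source: int
    sink: int
    optimal_path: list[int] | None
    optimal_weight: float
    paths: list[tuple[list[int], float]] = field(default_factory=list)
    tolerance: float = 0.0
    truncated: bool = False

    @property
    def reachable(self) -> bool:
        return self.optimal_path is not None


def shortest_path(net: DynamicNetwork, source: int, sink: int,
                  dist: np.ndarray | None = None) -> PathSet:
    """Minimal total-d_ij path via Floyd-Warshall distances with greedy
    reconstruction; among tied shortest paths the lexicographically smallest
    node sequence is returned.  An unreachable sink yields an explicit
    'no path' result rather than an exception."""
    for node in (source, sink):
        if not (0 <= node < net.n_nodes):
            raise ValueError(f"node {node} not in the network")
    if dist is None:
        dist = _floyd_warshall(net)
    if source == sink:
        return PathSet(source, sink, [source], 0.0, [([source], 0.0)])
    if not np.isfinite(dist[source, sink]):
        return PathSet(source, sink, None, np.inf, [])
    path = [source]
    u = source
    total = 0.0
    while u != sink:
        candidates = [
            v for v, w in sorted(net.neighbors(u).items())
            if abs(w + dist[v, sink] - dist[u, sink]) <= 1e-10
        ]
        v = candidates[0]  # sorted: lexicographically smallest continuation
        total += net.edge_weight(u, v)
        path.append(v)
        u = v
    return PathSet(source, sink, path, float(dist[source, sink]),
                   [(path, float(dist[source, sink]))])


def suboptimal_paths(
    net: DynamicNetwork,
    source: int,
    sink: int,
    tolerance: float,
    max_paths: int = 10_000,
    dist: np.ndarray | None = None,
) -> PathSet:
    """All simple paths within ``tolerance`` of the optimal weight.

    Bounded depth-first enumeration pruned with the Floyd-Warshall distance to
    the sink (an admissible bound, so no qualifying path is missed).  Paths
    are deduplicated and sorted by weight then lexicographically; enumeration
    stops with a truncation flag once ``max_paths`` paths are found.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if dist is None:
        dist = _floyd_warshall(net)
    base = shortest_path(net, source, sink, dist=dist)
    if not base.reachable:
        return base
    bound = base.optimal_weight + tolerance + 1e-10
    found: list[tuple[list[int], float]] = []
    truncated = False
    stack: list[tuple[int, float, list[int], set]] = [(source, 0.0, [source], {source})]
    while stack:
        u, acc, path, visited = stack.pop()
        if u == sink:
            found.append((path, acc))
            if len(found) >= max_paths:
                truncated = True
                break
            continue
        # push in reverse-sorted order so smaller nodes are explored first
        for v, w in sorted(net.neighbors(u).items(), reverse=True):
            if v in visited:
                continue
            nacc = acc + w
            if nacc + dist[v, sink] <= bound:
                stack.append((v, nacc, path + [v], visited | {v}))
    found.sort(key=lambda pw: (round(pw[1], 10), pw[0]))
    return PathSet(
        source=source,
        sink=sink,
        optimal_path=base.optimal_path,
        optimal_weight=base.optimal_weight,
        paths=found,
        tolerance=tolerance,
        truncated=truncated,
    )


def default_endpoints(
    topology: Topology,
    source_residue: int = 1441,
    sink_residues: Sequence[int] = (1346, 1394, 1455, 1490),
    mapping: dict | None = None,
) -> tuple[list[int], list[int]]:
    """Source/sink node sets: the mutation-site residue of each monomer as
    sources and the nucleotide-binding residues (P-loop, Switch II, G4 loop,
    G5 loop) of each monomer as sinks; fully overridable via ``mapping``
    ({(chain, residue_index): node}) or the residue arguments."""
    mapping = mapping or {}

    def resolve(chain: str, index: int) -> int:
        if (chain, index) in mapping:
            return int(mapping[(chain, index)])
        return topology.residue_position(index, chain=chain)

    chains = topology.chains
    sources = [resolve(c, source_residue) for c in chains]
    sinks = [resolve(c, s) for c in chains for s in sink_residues]
    return sources, sinks
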