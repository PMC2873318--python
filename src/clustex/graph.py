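"""Network weighting, gene-gene distances, Dijkstra and Yen's k-shortest paths.

Edges are weighted by the absolute Pearson correlation of their endpoint
genes' time courses, w(x,y) = |cor(x,y)|, and carry the derived distance
d(x,y) = 1 - w(x,y); both functions are injectable so an alternative form
(e.g. d = 1/w - 1) can be swapped without code change.  The gene-gene
distance is the shortest-path length under d, so strongly co-expressed
direct interactors are close and uncorrelated ones are at distance ~1 per
hop.

All path routines are deterministic: equal-length paths are ordered
lexicographically by their node sequence.  The k-shortest-path search is
Yen's loopless-deviation algorithm on top of a best-first Dijkstra that
returns the lexicographically minimal shortest path.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigurationError
from .expression import ExpressionStats
from .io_model import ExpressionMatrix, GeneNetwork

DISTANCE_ATTR = "distance"


@dataclass(frozen=True)
class WeightedPath:
    """A loopless path and its total edge distance."""

    nodes: tuple[str, ...]
    length: float

    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(p)) for p in zip(self.nodes[:-1], self.nodes[1:])]


@dataclass
class DistanceMatrix:
    """Symmetric shortest-path length matrix over an ordered gene list."""

    gene_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.d.shape != (n, n):
            raise ConfigurationError("distance matrix shape mismatch")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])


def weight_network(
    skeleton: GeneNetwork,
    matrix: ExpressionMatrix,
    *,
    stats: ExpressionStats | None = None,
    scale: str = "log2",
    eps: float = 1.0,
    retain_unmeasured: bool = False,
    weight_fn: Callable[[ExpressionStats, str, str], float] | None = None,
    distance_fn: Callable[[float], float] | None = None,
) -> GeneNetwork:
    """Attach expression-derived weight and distance attributes to every edge.

    By default the network is restricted to genes present in both the
    skeleton and the expression matrix (intersection mode).  With
    ``retain_unmeasured=True`` unmeasured genes stay as nodes and their
    incident edges get weight 0 / distance given by ``distance_fn(0)``.
    """
    stats = stats or ExpressionStats(matrix, scale=scale, eps=eps)
    distance_fn = distance_fn or (lambda w: 1.0 - w)
    measured = {g for g in skeleton.graph.nodes() if stats.has(g)}
    if not measured:
        raise ConfigurationError("no overlap between network nodes and expression genes")

    if retain_unmeasured:
        g = skeleton.graph.copy()
    else:
        g = skeleton.graph.subgraph(measured).copy()

    pairs = [(u, v) for u, v in g.edges() if u in measured and v in measured]
    if weight_fn is None:
        weights = stats.abs_corr_edges(pairs)
    else:
        weights = np.array([weight_fn(stats, u, v) for u, v in pairs])
    computed = dict(zip(pairs, weights))
    for u, v in g.edges():
        w = computed.get((u, v), 0.0)  # unmeasured endpoints get weight 0
        w = float(min(max(w, 0.0), 1.0))
        g[u][v]["weight"] = w
        g[u][v][DISTANCE_ATTR] = float(distance_fn(w))
    return GeneNetwork(g)


def _check_distances(network: GeneNetwork) -> None:
    for u, v, data in network.graph.edges(data=True):
        d = data.get(DISTANCE_ATTR)
        if d is None:
            raise ConfigurationError(f"edge ({u},{v}) has no distance; weight the network first")
        if d < 0:
            raise ConfigurationError(f"edge ({u},{v}) has negative distance {d}")


def shortest_path_lengths(
    network: GeneNetwork,
    sources: Iterable[str],
    targets: Iterable[str] | None = None,
) -> DistanceMatrix:
    """Exact Dijkstra shortest-path lengths; unreachable pairs get infinity."""
    sources = sorted(set(sources))
    targets = sources if targets is None else sorted(set(targets))
    _check_distances(network)
    for gene in set(sources) | set(targets):
        if not network.has_node(gene):
            raise ConfigurationError(f"gene {gene!r} not in network")
    d = np.full((len(sources), len(targets)), np.inf)
    tgt_index = {g: j for j, g in enumerate(targets)}
    for i, s in enumerate(sources):
        lengths = nx.single_source_dijkstra_path_length(
            network.graph, s, weight=DISTANCE_ATTR
        )
        for g, length in lengths.items():
            j = tgt_index.get(g)
            if j is not None:
                d[i, j] = length
    if sources == targets:
        np.fill_diagonal(d, 0.0)
        d = np.minimum(d, d.T)  # exact symmetry against float asymmetries
    return DistanceMatrix(sources, d)


# ---------------------------------------------------------------------------
# Deterministic (lexicographically minimal) Dijkstra
# ---------------------------------------------------------------------------

def dijkstra_path_lex(
    graph: nx.Graph,
    s: str,
    t: str,
    *,
    excluded_nodes: frozenset[str] | set[str] = frozenset(),
    excluded_edges: frozenset[tuple[str, str]] | set[tuple[str, str]] = frozenset(),
) -> tuple[tuple[str, ...], float] | None:
    """Shortest s->t path; among equal-length optima the lexicographically
    smallest node sequence.  Returns None if t is unreachable.

    Best-first search over (length, node-sequence) keys: the first completed
    path popped for t is both shortest and lexicographically minimal, because
    every prefix of a lexicographically smaller equal-length path sorts ahead
    of the popped key.  ``excluded_edges`` are directed (u, v) pairs.
    """
    if s == t:
        return (s,), 0.0
    settled: set[str] = set()
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (s,))]
    while heap:
        length, path = heapq.heappop(heap)
        v = path[-1]
        if v in settled:
            continue
        settled.add(v)
        if v == t:
            return path, length
        for u in sorted(graph[v]):
            if u in settled or u in excluded_nodes or (v, u) in excluded_edges:
                continue
            heapq.heappush(heap, (length + graph[v][u][DISTANCE_ATTR], path + (u,)))
    return None


def _path_length(graph: nx.Graph, nodes: Sequence[str]) -> float:
    return float(sum(graph[u][v][DISTANCE_ATTR] for u, v in zip(nodes[:-1], nodes[1:])))


def k_shortest_paths(network: GeneNetwork, s: str, t: str, k: int) -> list[WeightedPath]:
    """Yen's algorithm: up to k loopless s->t paths in (length, sequence) order.

    The first path is the deterministic Dijkstra shortest path; candidate
    deviations are pooled in a heap keyed by (length, node sequence), which
    both deduplicates and fixes the tie order.  If fewer than k loopless
    paths exist, all of them are returned.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    graph = network.graph
    for gene in (s, t):
        if not graph.has_node(gene):
            raise ConfigurationError(f"gene {gene!r} not in network")
    if s == t:
        raise ConfigurationError("k-shortest paths require distinct endpoints")
    _check_distances(network)

    first = dijkstra_path_lex(graph, s, t)
    if first is None:
        return []
    accepted: list[tuple[float, tuple[str, ...]]] = [(first[1], first[0])]
    candidates: list[tuple[float, tuple[str, ...]]] = []
    seen: set[tuple[str, ...]] = {first[0]}

    while len(accepted) < k:
        _, prev = accepted[-1]
        for j in range(len(prev) - 1):
            root = prev[: j + 1]
            spur = prev[j]
            excluded_edges = {
                (p[j], p[j + 1]) for _, p in accepted if len(p) > j + 1 and p[: j + 1] == root
            }
            excluded_nodes = set(root[:-1])
            spur_result = dijkstra_path_lex(
                graph, spur, t,
                excluded_nodes=excluded_nodes,
                excluded_edges=excluded_edges,
            )
            if spur_result is None:
                continue
            spur_path, _ = spur_result
            total = root[:-1] + spur_path
            if total in seen:
                continue
            seen.add(total)
            heapq.heappush(candidates, (_path_length(graph, total), total))
        if not candidates:
            break
        accepted.append(heapq.heappop(candidates))
    return [WeightedPath(nodes=p, length=length) for length, p in accepted]


def enumerate_paths_bruteforce(
    network: GeneNetwork, s: str, t: str, max_nodes: int = 12
) -> list[WeightedPath]:
    """Exhaustively enumerate all loopless s->t paths (test oracle).

    Refuses networks with more than ``max_nodes`` nodes.  Output is sorted by
    (length, node sequence) — the same order the k-shortest-path search must
    reproduce.
    """
    graph = network.graph
    if graph.number_of_nodes() > max_nodes:
        raise ConfigurationError(
            f"brute-force enumeration limited to {max_nodes} nodes, "
            f"got {graph.number_of_nodes()}"
        )
    for gene in (s, t):
        if not graph.has_node(gene):
            raise ConfigurationError(f"gene {gene!r} not in network")
    _check_distances(network)
    paths = [
        WeightedPath(nodes=tuple(p), length=_path_length(graph, p))
        for p in nx.all_simple_paths(graph, s, t)
    ]
    return sorted(paths, key=lambda p: (p.length, p.nodes))
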