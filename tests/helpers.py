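"""Shared test utilities: graph builders and independent brute-force oracles."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from clustex import ExpressionMatrix, GeneNetwork


def weighted_network(edges: list[tuple[str, str, float]]) -> GeneNetwork:
    """Build a GeneNetwork from (u, v, distance) triples."""
    g = nx.Graph()
    for u, v, d in edges:
        g.add_edge(u, v, distance=float(d), weight=float(max(0.0, min(1.0, 1.0 - d))))
    return GeneNetwork(g)


def random_weighted_network(
    rng: np.random.Generator, n_min: int = 4, n_max: int = 10, p: float = 0.5
) -> GeneNetwork:
    """Random G(n, p) graph with uniform (0.01, 1] edge distances."""
    n = int(rng.integers(n_min, n_max + 1))
    base = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.Graph()
    g.add_nodes_from(f"N{i}" for i in range(n))
    for u, v in base.edges():
        g.add_edge(f"N{u}", f"N{v}", distance=float(rng.uniform(0.01, 1.0)))
    return GeneNetwork(g)


def matrix_from_rows(rows: dict[str, list[float]], baseline_index: int = 0) -> ExpressionMatrix:
    labels = [f"t{i}" for i in range(len(next(iter(rows.values()))))]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=labels, dtype=float)
    return ExpressionMatrix(df, baseline_index)


def upgma_bruteforce(gene_ids: list[str], d: np.ndarray) -> list[tuple[tuple, tuple, float]]:
    """Recompute-all-averages agglomeration (independent of Lance-Williams).

    Cluster-cluster distance = mean over all leaf pairs on the original
    matrix; ties broken by the pair whose smallest member sorts first, then
    by the partner cluster's smallest member.  Infinite averages never merge.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    clusters: list[tuple[str, ...]] = [(g,) for g in gene_ids]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pairs = [d[index[a], index[b]] for a in clusters[i] for b in clusters[j]]
                avg = float(np.mean(pairs))
                if not math.isfinite(avg):
                    continue
                key = (avg, tuple(sorted((clusters[i][0], clusters[j][0]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        (height, _), i, j = best[0], best[1], best[2]
        a, b = sorted((clusters[i], clusters[j]))
        merges.append((a, b, height))
        merged = tuple(sorted(clusters[i] + clusters[j]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges
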