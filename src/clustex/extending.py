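"""Module recovery: extend each DE-gene cluster with intermediate genes.

Three stages per cluster, mirroring the workflow's cost-bounded search space:

1. *Shortest-path union*: one deterministic Dijkstra shortest path per
   unordered DE pair; its nodes plus the cluster form a connected
   sub-network.
2. *One-step extension*: add every direct network neighbor of stage-1 nodes.
   Stages 1-2 bound the search space for the expensive step 3.
3. *k-shortest-path extraction*: within the stage-2 subnetwork, take the
   union of all genes and edges on the top-k loopless paths between every
   DE pair (k = 10 by default).

Gene provenance is recorded per module gene: ``de`` (cluster member),
``shortest_path`` (stage-1 intermediate) or ``k_shortest`` (recovered only
by 2nd..k-th shortest paths).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .clustering import ClusterPartition
from .errors import ConfigurationError
from .graph import WeightedPath, dijkstra_path_lex, k_shortest_paths
from .io_model import GeneNetwork, ResponsiveModule


@dataclass
class ExtensionTrace:
    """Record of one cluster's staged extension (cluster ⊆ stage1 ⊆ stage2)."""

    cluster: frozenset[str]
    stage1_nodes: frozenset[str]
    stage2_nodes: frozenset[str]
    module: ResponsiveModule
    k: int


def _component_groups(network: GeneNetwork, cluster: frozenset[str]) -> list[list[str]]:
    for gene in cluster:
        if not network.has_node(gene):
            raise ConfigurationError(f"cluster gene {gene!r} not in network")
    comp_of: dict[str, int] = {}
    for idx, comp in enumerate(nx.connected_components(network.graph)):
        for node in comp:
            comp_of[node] = idx
    groups: dict[int, list[str]] = {}
    for gene in sorted(cluster):
        groups.setdefault(comp_of[gene], []).append(gene)
    if len(groups) > 1:
        warnings.warn(
            f"cluster spans {len(groups)} network components; processed per component"
        )
    return [groups[i] for i in sorted(groups)]


def shortest_path_union(network: GeneNetwork, cluster: frozenset[str]) -> frozenset[str]:
    """Nodes on one deterministic shortest path per DE pair, plus the cluster.

    Pairs in different components are handled per component (with a warning
    from the grouping step); the lexicographically minimal shortest path
    makes the union reproducible across runs.
    """
    nodes: set[str] = set(cluster)
    for group in _component_groups(network, cluster):
        for a, b in combinations(group, 2):
            result = dijkstra_path_lex(network.graph, a, b)
            if result is not None:
                nodes.update(result[0])
    return frozenset(nodes)


def one_step_extension(network: GeneNetwork, nodes: frozenset[str]) -> frozenset[str]:
    """The node set plus all of its direct network neighbors."""
    extended = set(nodes)
    for node in nodes:
        if network.has_node(node):
            extended.update(network.graph[node])
    return frozenset(extended)


def _pair_paths(
    subnetwork: GeneNetwork, cluster: frozenset[str], k: int
) -> dict[tuple[str, str], list[WeightedPath]]:
    """Top-k loopless paths per unordered DE pair inside the subnetwork."""
    paths: dict[tuple[str, str], list[WeightedPath]] = {}
    for a, b in combinations(sorted(cluster), 2):
        found = k_shortest_paths(subnetwork, a, b, k)
        if not found:
            warnings.warn(f"DE pair ({a},{b}) unreachable in extended subnetwork; skipped")
            continue
        paths[(a, b)] = found
    return paths


def _assemble_module(
    module_id: str,
    cluster: frozenset[str],
    stage1_nodes: frozenset[str],
    pair_paths: dict[tuple[str, str], list[WeightedPath]],
    k: int,
) -> ResponsiveModule:
    genes: set[str] = set(cluster)
    edges: set[tuple[str, str]] = set()
    for paths in pair_paths.values():
        for path in paths[:k]:
            genes.update(path.nodes)
            edges.update(path.edges())
    provenance = {}
    for gene in genes:
        if gene in cluster:
            provenance[gene] = "de"
        elif gene in stage1_nodes:
            provenance[gene] = "shortest_path"
        else:
            provenance[gene] = "k_shortest"
    return ResponsiveModule(
        module_id=module_id,
        genes=frozenset(genes),
        de_genes=frozenset(cluster),
        provenance=provenance,
        edges=tuple(sorted(edges)),
    )


def extract_module(
    subnetwork: GeneNetwork,
    cluster: frozenset[str],
    k: int = 10,
    *,
    stage1_nodes: frozenset[str] | None = None,
    module_id: str = "module",
) -> ResponsiveModule:
    """Union of genes/edges on the top-k paths of every DE pair (restricted
    to the given stage-2 subnetwork)."""
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    stage1 = stage1_nodes if stage1_nodes is not None else frozenset(cluster)
    return _assemble_module(module_id, cluster, stage1, _pair_paths(subnetwork, cluster, k), k)


def extend_cluster(
    network: GeneNetwork, cluster: frozenset[str], k: int = 10, module_id: str = "module"
) -> ExtensionTrace:
    """Run all three extension stages for one DE cluster."""
    if not cluster:
        raise ConfigurationError("cannot extend an empty cluster")
    stage1 = shortest_path_union(network, cluster)
    stage2 = one_step_extension(network, stage1)
    sub = network.subgraph(stage2)
    module = extract_module(sub, cluster, k, stage1_nodes=stage1, module_id=module_id)
    return ExtensionTrace(
        cluster=frozenset(cluster),
        stage1_nodes=stage1,
        stage2_nodes=stage2,
        module=module,
        k=k,
    )


def k_curve(
    network: GeneNetwork,
    cluster: frozenset[str],
    k_grid: list[int],
    growth_ratio_threshold: float = 5.0,
) -> list[dict]:
    """Module size as a function of k plus the advisory growth-ratio flag.

    Because the top-k path list for each pair is a prefix of the top-k_max
    list, paths are computed once at k_max and re-unioned per k.  The flag at
    k reports whether the growth from the bare cluster to k is at least
    ``growth_ratio_threshold`` times the growth from k to 2k (computable only
    when 2k is inside the grid's reach); it is advisory, never enforced.
    """
    if any(b <= a for a, b in zip(k_grid, k_grid[1:])) or not k_grid:
        raise ConfigurationError("k grid must be non-empty, strictly ascending")
    if k_grid[0] < 1:
        raise ConfigurationError("k must be >= 1")
    k_max = k_grid[-1]
    stage1 = shortest_path_union(network, cluster)
    stage2 = one_step_extension(network, stage1)
    sub = network.subgraph(stage2)
    pair_paths = _pair_paths(sub, cluster, k_max)

    def size_at(k: int) -> int:
        genes: set[str] = set(cluster)
        for paths in pair_paths.values():
            for path in paths[:k]:
                genes.update(path.nodes)
        return len(genes)

    sizes = {k: size_at(k) for k in sorted(set(k_grid) | {2 * k for k in k_grid if 2 * k <= k_max})}
    rows = []
    base = len(cluster)
    for k in k_grid:
        row: dict = {"k": k, "module_size": sizes[k]}
        if 2 * k in sizes:
            low = sizes[k] - base
            high = sizes[2 * k] - sizes[k]
            ratio = float("inf") if high == 0 else low / high
            row["growth_ratio"] = ratio
            row["growth_flag"] = ratio >= growth_ratio_threshold
        else:
            row["growth_ratio"] = None
            row["growth_flag"] = None
        rows.append(row)
    return rows


def write_k_curve(rows: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tmodule_size\tgrowth_ratio\tgrowth_ratio_flag\n")
        for row in rows:
            ratio = "NA" if row["growth_ratio"] is None else f"{row['growth_ratio']:.4g}"
            flag = "NA" if row["growth_flag"] is None else str(int(row["growth_flag"]))
            fh.write(f"{row['k']}\t{row['module_size']}\t{ratio}\t{flag}\n")


def run_all_clusters(
    network: GeneNetwork,
    partition: ClusterPartition,
    k: int = 10,
    min_de: int = 5,
) -> list[ExtensionTrace]:
    """Extend every cluster with at least ``min_de`` DE genes.

    Returns traces ordered by module size descending (ties by the module's
    lexicographically smallest gene), with module ids M1, M2, ... assigned
    after ordering.
    """
    eligible = [frozenset(c) for c in partition.clusters if len(c) >= min_de]
    if not eligible:
        raise ConfigurationError(
            f"no DE cluster has >= {min_de} genes; lower min_de or the fold threshold"
        )
    traces = [extend_cluster(network, cluster, k) for cluster in eligible]
    traces.sort(key=lambda t: (-t.module.size, min(t.module.genes)))
    renamed = []
    for idx, trace in enumerate(traces, start=1):
        module = trace.module
        renamed.append(
            ExtensionTrace(
                cluster=trace.cluster,
                stage1_nodes=trace.stage1_nodes,
                stage2_nodes=trace.stage2_nodes,
                module=ResponsiveModule(
                    module_id=f"M{idx}",
                    genes=module.genes,
                    de_genes=module.de_genes,
                    provenance=module.provenance,
                    edges=module.edges,
                ),
                k=trace.k,
            )
        )
    return renamed
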