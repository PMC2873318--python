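"""Synthetic networks, time-course expression and gene sets with planted modules.

The generator emulates the statistical structure the workflow assumes: a
scale-free PPI-like network, a handful of planted responsive modules —
connected subgraphs whose genes share a latent time-course response and are
therefore co-expressed — and background genes that only carry noise.

Expression is simulated on the log2 scale and exponentiated to raw signal
values:

    log2 x_g(t) = baseline_g + s_g * b_g * r(t) + N(0, sigma_g)

where r(t) is the module's response curve (saturating rise or transient
pulse, peak-normalized to 1), s_g a random sign (up/down regulation) and
b_g the per-gene amplitude: for the module's DE fraction, b_g = log2 of a
fold drawn from ``fc_range`` (so those genes exceed the fold threshold);
for the rest, a sub-threshold fold in [1.1, 1.4].  Module-gene noise
sigma_g is derived from the target intra-module correlation ``rho_in``
(sigma_g = b_g * sqrt(VarR * (1 - rho)/rho), giving pairwise |Pearson|
~= rho_in); ``noise_sd`` is the technical noise of background genes and the
reference level against which an unattainable rho_in triggers a warning.
Baseline log2 level ~ N(7, 0.5) (signal ~128), so the signal floor of 1 is
negligible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_model import (
    ExpressionMatrix,
    GeneNetwork,
    GeneSetCollection,
    write_expression,
    write_gmt,
    write_network,
)

RESPONSE_CURVES = ("rise", "pulse")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_network(
    n_genes: int,
    model: str = "preferential_attachment",
    m: int = 3,
    p: float | None = None,
    seed: int = 0,
) -> GeneNetwork:
    """Random gene network skeleton.

    ``preferential_attachment`` gives a connected scale-free graph with
    heavy-tailed degrees (PPI-like); ``erdos_renyi`` is the homogeneous
    control, reduced to its largest component (with a warning) if the draw
    is disconnected.
    """
    if n_genes < 10:
        raise ConfigurationError("need at least 10 genes")
    ids = _gene_ids(n_genes)
    if model == "preferential_attachment":
        g = nx.barabasi_albert_graph(n_genes, m, seed=seed)
    elif model == "erdos_renyi":
        p = p if p is not None else 2.0 * m / (n_genes - 1)
        g = nx.gnp_random_graph(n_genes, p, seed=seed)
        if not nx.is_connected(g):
            warnings.warn("disconnected Erdos-Renyi draw; keeping the largest component")
            largest = max(nx.connected_components(g), key=len)
            g = g.subgraph(largest).copy()
    else:
        raise ConfigurationError(f"unknown network model {model!r}")
    return GeneNetwork(nx.relabel_nodes(g, {i: ids[i] for i in g.nodes()}))


def plant_modules(
    network: GeneNetwork,
    n_modules: int,
    size: int,
    seed: int = 0,
    max_tries: int = 200,
) -> list[frozenset[str]]:
    """Disjoint connected subgraphs induced by random walks.

    Each module is the set of distinct nodes visited by a random walk
    (restricted to nodes unused by previous modules) until ``size`` nodes
    have been collected.  Walks revisit nodes freely, so the induced
    subgraph is connected and — because walks are degree-biased and loop
    locally — considerably denser than a tree: most module genes sit on
    internal cycles rather than dangling as leaves.
    """
    if n_modules * size > network.n_nodes:
        raise ConfigurationError("planted modules would exceed the network size")
    rng = np.random.default_rng(seed)
    graph = network.graph
    used: set[str] = set()
    modules: list[frozenset[str]] = []
    max_steps = 400 * size
    for _ in range(n_modules):
        for _attempt in range(max_tries):
            candidates = sorted(set(graph.nodes()) - used)
            node = candidates[rng.integers(len(candidates))]
            visited = {node}
            for _step in range(max_steps):
                if len(visited) >= size:
                    break
                neighbors = sorted(set(graph[node]) - used)
                if not neighbors:
                    break  # walked into a dead end; restart
                node = neighbors[rng.integers(len(neighbors))]
                visited.add(node)
            if len(visited) == size:
                modules.append(frozenset(visited))
                used |= visited
                break
        else:
            raise ConfigurationError(
                f"could not grow a connected module of size {size} in {max_tries} tries"
            )
    return modules


def _response_curve(kind: str, n_timepoints: int, tau: float = 0.3) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_timepoints)
    if kind == "rise":
        r = 1.0 - np.exp(-t / tau)
    elif kind == "pulse":
        r = (t / tau) * np.exp(1.0 - t / tau)
    else:
        raise ConfigurationError(f"unknown response curve {kind!r}")
    return r / r.max()


@dataclass
class GroundTruth:
    """Generator bookkeeping for recovery tests."""

    planted_modules: list[frozenset[str]]
    de_genes: list[frozenset[str]]          # per module, the above-threshold members
    amplitudes: dict[str, float]            # b_g (log2 fold amplitude)
    signs: dict[str, int]
    response_curves: list[dict]             # per module: {"kind": ..., "tau": ...}
    params: dict = field(default_factory=dict)


def generate_expression(
    network: GeneNetwork,
    planted: list[frozenset[str]],
    n_timepoints: int = 25,
    rho_in: float = 0.8,
    fc_range: tuple[float, float] = (2.5, 6.0),
    de_fraction: float = 0.6,
    noise_sd: float = 0.15,
    seed: int = 0,
    curve: str = "auto",
    baseline_log2: float = 7.0,
    nonde_fold_range: tuple[float, float] = (1.1, 1.4),
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Time-course signals with planted co-expressed DE modules.

    ``curve="auto"`` (default) gives each planted module its own response —
    alternating saturating-rise / transient-pulse kinds with a per-module
    time constant — so distinct modules are co-expressed internally but not
    with each other, matching the "relatively separate responsive modules"
    picture.  An explicit ``"rise"`` or ``"pulse"`` applies one fixed curve
    (tau = 0.3) to every module.
    """
    if not (0.0 <= rho_in < 1.0):
        raise ConfigurationError("rho_in must be in [0, 1)")
    if fc_range[0] < 1.0 or fc_range[1] < fc_range[0]:
        raise ConfigurationError("fc_range must satisfy 1 <= low <= high")
    if n_timepoints < 2:
        raise ConfigurationError("need at least 2 time points")
    if curve not in RESPONSE_CURVES + ("auto",):
        raise ConfigurationError(f"unknown response curve {curve!r}")
    rng = np.random.default_rng(seed)
    genes = network.node_list()
    n = len(genes)
    curve_specs: list[dict] = []
    responses: list[np.ndarray] = []
    for i in range(len(planted)):
        if curve == "auto":
            kind = RESPONSE_CURVES[i % len(RESPONSE_CURVES)]
            tau = float(rng.uniform(0.2, 0.4))
        else:
            kind, tau = curve, 0.3
        curve_specs.append({"kind": kind, "tau": round(tau, 6)})
        responses.append(_response_curve(kind, n_timepoints, tau))

    amplitudes: dict[str, float] = {}
    signs: dict[str, int] = {}
    sigma: dict[str, float] = {}
    de_sets: list[frozenset[str]] = []
    module_genes: set[str] = set()
    module_of: dict[str, int] = {}
    unattainable = 0
    min_attainable_rho = 1.0

    for mi, module in enumerate(planted):
        members = sorted(module)
        module_genes |= set(members)
        module_of.update({g: mi for g in members})
        var_r = float(np.var(responses[mi], ddof=1))
        n_de = int(round(de_fraction * len(members)))
        de_members = set(
            np.array(members, dtype=object)[
                rng.choice(len(members), size=n_de, replace=False)
            ]
        )
        de_sets.append(frozenset(de_members))
        for gene in members:
            if gene in de_members:
                fold = rng.uniform(*fc_range)
            else:
                fold = rng.uniform(*nonde_fold_range)
            b = float(np.log2(fold))
            amplitudes[gene] = b
            signs[gene] = int(rng.integers(2)) * 2 - 1
            if noise_sd == 0.0 or rho_in == 0.0:
                sigma[gene] = 0.0 if noise_sd == 0.0 else noise_sd
                continue
            s = b * np.sqrt(var_r * (1.0 - rho_in) / rho_in)
            if s < noise_sd:
                unattainable += 1
                min_attainable_rho = min(
                    min_attainable_rho,
                    b**2 * var_r / (b**2 * var_r + noise_sd**2),
                )
            sigma[gene] = float(s)
    if noise_sd == 0.0 and rho_in not in (0.0,):
        warnings.warn(
            f"noise_sd=0 gives intra-module |cor|=1 exactly; rho_in={rho_in} ignored"
        )
    elif unattainable:
        warnings.warn(
            f"{unattainable} module genes need noise below noise_sd={noise_sd} to reach "
            f"rho_in={rho_in} (attainable rho at noise_sd: >= {min_attainable_rho:.2f}); "
            "using the rho-derived noise"
        )

    baselines = rng.normal(baseline_log2, 0.5, size=n)
    log2x = np.tile(baselines[:, None], (1, n_timepoints))
    idx = {g: i for i, g in enumerate(genes)}
    for gene in sorted(module_genes):
        i = idx[gene]
        log2x[i] += signs[gene] * amplitudes[gene] * responses[module_of[gene]]
        if sigma[gene] > 0:
            log2x[i] += rng.normal(0.0, sigma[gene], size=n_timepoints)
    background = sorted(set(genes) - module_genes)
    if noise_sd > 0 and background:
        rows = np.array([idx[g] for g in background])
        log2x[rows] += rng.normal(0.0, noise_sd, size=(len(rows), n_timepoints))

    labels = [f"t{i:02d}" for i in range(n_timepoints)]
    df = pd.DataFrame(np.power(2.0, log2x), index=genes, columns=labels)
    matrix = ExpressionMatrix(df, baseline_index=0)
    truth = GroundTruth(
        planted_modules=[frozenset(m) for m in planted],
        de_genes=de_sets,
        amplitudes=amplitudes,
        signs=signs,
        response_curves=curve_specs,
        params={
            "n_timepoints": n_timepoints,
            "rho_in": rho_in,
            "fc_range": list(fc_range),
            "de_fraction": de_fraction,
            "noise_sd": noise_sd,
            "baseline_log2": baseline_log2,
            "seed": seed,
        },
    )
    return matrix, truth


def generate_gene_sets(
    planted: list[frozenset[str]],
    de_sets: list[frozenset[str]],
    universe: frozenset[str] | set[str],
    network: GeneNetwork,
    n_decoys: int = 20,
    seed: int = 0,
) -> GeneSetCollection:
    """One "true" set per planted module (its DE core + 20% random padding)
    plus degree-matched decoy sets of comparable size."""
    universe = frozenset(universe)
    for module in planted:
        if not module <= universe:
            raise ConfigurationError("universe must cover all planted genes")
    rng = np.random.default_rng(seed)
    universe_list = np.array(sorted(universe), dtype=object)
    sets: dict[str, frozenset[str]] = {}
    true_sizes: list[int] = []
    for i, core in enumerate(de_sets, start=1):
        n_pad = max(1, int(round(0.2 * len(core))))
        outside = np.array(sorted(universe - core), dtype=object)
        pad = set(outside[rng.choice(len(outside), size=n_pad, replace=False)])
        sets[f"TRUE_SET_{i}"] = frozenset(core | pad)
        true_sizes.append(len(core) + n_pad)

    # decoys: degree-matched to a randomly chosen true-set size (+/- 20%)
    from .enrichment import DegreePreservingSampler

    sampler = DegreePreservingSampler(network, universe)
    for j in range(1, n_decoys + 1):
        base = int(true_sizes[rng.integers(len(true_sizes))])
        size = max(3, int(round(base * rng.uniform(0.8, 1.2))))
        seed_set = frozenset(
            universe_list[rng.choice(len(universe_list), size=size, replace=False)]
        )
        sets[f"DECOY_{j:02d}"] = sampler.sample_sets(seed_set, 1, rng)[0]
    return GeneSetCollection(sets=sets, universe=universe)


@dataclass
class SyntheticScenario:
    network: GeneNetwork
    expression: ExpressionMatrix
    truth: GroundTruth
    gene_sets: GeneSetCollection
    seed: int


def default_scenario(
    seed: int = 0,
    n_genes: int = 500,
    n_modules: int = 2,
    module_size: int = 30,
    n_timepoints: int = 25,
    rho_in: float = 0.8,
    de_fraction: float = 0.6,
    noise_sd: float = 0.15,
    m: int = 3,
    model: str = "preferential_attachment",
    curve: str = "auto",
    n_decoys: int = 20,
) -> SyntheticScenario:
    """The standard benchmark scenario: 500 genes, two planted 30-gene
    modules, target intra-module |cor| 0.8, 25 time points.

    Set ``n_modules=0`` for the pure-noise control scenario.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4)
    network = generate_network(n_genes, model=model, m=m, seed=int(sub_seeds[0]))
    planted = plant_modules(network, n_modules, module_size, seed=int(sub_seeds[1]))
    expression, truth = generate_expression(
        network,
        planted,
        n_timepoints=n_timepoints,
        rho_in=rho_in,
        de_fraction=de_fraction,
        noise_sd=noise_sd,
        seed=int(sub_seeds[2]),
        curve=curve,
    )
    universe = frozenset(network.graph.nodes())
    if planted:
        gene_sets = generate_gene_sets(
            planted, truth.de_genes, universe, network,
            n_decoys=n_decoys, seed=int(sub_seeds[3]),
        )
    else:
        gene_sets = GeneSetCollection(sets={"DECOY_01": frozenset(list(universe)[:10])},
                                      universe=universe)
    return SyntheticScenario(
        network=network, expression=expression, truth=truth,
        gene_sets=gene_sets, seed=seed,
    )


def write_scenario(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write a scenario in the pipeline's input formats + a truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "network": out / "network.sif",
        "gene_sets": out / "gene_sets.gmt",
        "manifest": out / "manifest.json",
    }
    write_expression(scenario.expression, paths["expression"])
    write_network(scenario.network, paths["network"])
    write_gmt(scenario.gene_sets, paths["gene_sets"])
    for i, module in enumerate(scenario.truth.planted_modules, start=1):
        ref = out / f"reference_module_{i}.txt"
        ref.write_text("".join(f"{g}\n" for g in sorted(module)))
        paths[f"reference_{i}"] = ref
    manifest = {
        "seed": scenario.seed,
        "n_genes": scenario.network.n_nodes,
        "n_edges": scenario.network.n_edges,
        "planted_modules": [sorted(m) for m in scenario.truth.planted_modules],
        "de_genes": [sorted(m) for m in scenario.truth.de_genes],
        "amplitudes": {g: round(b, 6) for g, b in sorted(scenario.truth.amplitudes.items())},
        "signs": dict(sorted(scenario.truth.signs.items())),
        "response_curves": scenario.truth.response_curves,
        "params": scenario.truth.params,
    }
    with paths["manifest"].open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
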