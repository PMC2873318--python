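"""End-to-end orchestration: DE selection -> clustering -> extension -> scoring.

This is the library core behind the ``clustex run`` command and the
programmatic entry point for benchmarks: it takes an expression matrix and
a network skeleton, runs the two-step workflow under a :class:`RunConfig`,
and returns every intermediate artifact (DE genes, distance matrix,
dendrogram, cutoff curve, partition, extension traces, module scores).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clustering import (
    ClusterPartition,
    Dendrogram,
    average_linkage,
    cutoff_curve,
    default_grid,
    partition_at_cutoff,
    suggest_cutoff,
    write_cutoff_curve,
)
from .config import RunConfig, substream_seed
from .errors import ConfigurationError
from .expression import ExpressionStats, select_de_genes
from .extending import ExtensionTrace, run_all_clusters, write_k_curve, k_curve
from .graph import DistanceMatrix, shortest_path_lengths, weight_network
from .io_model import ExpressionMatrix, GeneNetwork, ResponsiveModule, collapse_probes, write_module
from .scoring import ModuleScore, module_zscore, write_score_report

logger = logging.getLogger("clustex")


@dataclass
class PipelineResult:
    config: RunConfig
    stats: ExpressionStats
    network: GeneNetwork                  # weighted, analysis universe
    de_genes: frozenset[str]
    de_in_network: frozenset[str]
    distance_matrix: DistanceMatrix
    dendrogram: Dendrogram
    curve: list[tuple[float, int]]
    suggested_cutoff: float | None
    cutoff: float
    partition: ClusterPartition
    traces: list[ExtensionTrace]
    scores: list[ModuleScore] = field(default_factory=list)

    @property
    def modules(self) -> list[ResponsiveModule]:
        return [t.module for t in self.traces]

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.network.graph.nodes())


def run_pipeline(
    matrix: ExpressionMatrix,
    skeleton: GeneNetwork,
    config: RunConfig | None = None,
    *,
    score_modules: bool = True,
) -> PipelineResult:
    """Run the full two-step workflow.

    Raises :class:`ConfigurationError` when no DE gene survives the fold
    threshold, or when no DE cluster reaches ``min_de`` (both indicate the
    thresholds do not fit the dataset).  With ``cutoff="auto"`` the knee of
    the cluster-growth curve is applied; callers wanting the advisory-only
    behavior (as the CLI enforces) should inspect ``suggested_cutoff``.
    """
    config = config or RunConfig()
    t0 = time.perf_counter()
    matrix = collapse_probes(matrix)
    stats = ExpressionStats(matrix, scale=config.correlation_scale, eps=config.signal_floor)

    de_genes = select_de_genes(matrix, config.min_fold, eps=config.signal_floor)
    if not de_genes:
        raise ConfigurationError(
            f"no DE genes at min_fold={config.min_fold}; lower the threshold"
        )
    logger.info("DE genes: %d of %d (min_fold=%g)", len(de_genes), matrix.n_genes, config.min_fold)

    network = weight_network(
        skeleton,
        matrix,
        stats=stats,
        retain_unmeasured=config.retain_unmeasured,
    )
    de_in_network = frozenset(g for g in de_genes if network.has_node(g))
    dropped = len(de_genes) - len(de_in_network)
    if dropped:
        logger.info("%d DE genes absent from the network were dropped", dropped)
    if not de_in_network:
        raise ConfigurationError("no DE gene is present in the network")

    dist = shortest_path_lengths(network, de_in_network)
    dend = average_linkage(dist)
    grid = default_grid(dend, config.cutoff_grid_points)
    curve = cutoff_curve(dend, grid)
    suggested = None
    if len(curve) >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            suggested = suggest_cutoff(curve)
    if config.cutoff == "auto":
        if suggested is None:
            raise ConfigurationError("cutoff curve too short to suggest a cutoff; set one")
        cutoff = suggested
        logger.info("auto cutoff: %g", cutoff)
    else:
        cutoff = float(config.cutoff)
    partition = partition_at_cutoff(dend, cutoff)
    logger.info(
        "partition at cutoff %g: %d clusters, biggest %d",
        cutoff, len(partition.clusters), max(partition.sizes(), default=0),
    )

    traces = run_all_clusters(network, partition, k=config.k, min_de=config.min_de)
    logger.info("modules: %s", [t.module.size for t in traces])

    scores: list[ModuleScore] = []
    if score_modules:
        score_seed = substream_seed(config.seed, "scoring")
        for trace in traces:
            if not trace.module.edges:
                warnings.warn(f"module {trace.module.module_id} has no edges; not scored")
                continue
            scores.append(
                module_zscore(
                    trace.module, network, stats,
                    n_samples=config.n_edge_samples, seed=score_seed,
                )
            )
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return PipelineResult(
        config=config,
        stats=stats,
        network=network,
        de_genes=de_genes,
        de_in_network=de_in_network,
        distance_matrix=dist,
        dendrogram=dend,
        curve=curve,
        suggested_cutoff=suggested,
        cutoff=cutoff,
        partition=partition,
        traces=traces,
        scores=scores,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_provenance(
    out_dir: Path, config: RunConfig, inputs: dict[str, Path], extra: dict | None = None
) -> Path:
    """Machine-readable record sufficient to reproduce a run (no wall-clock
    data, so outputs stay byte-identical across reruns)."""
    record = {
        "tool": "clustex",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {name: {"path": str(p), "sha256": _sha256(Path(p))} for name, p in inputs.items()},
    }
    if extra:
        record.update(extra)
    path = Path(out_dir) / "provenance.json"
    with path.open("w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_run_outputs(
    result: PipelineResult,
    out_dir: str | Path,
    *,
    with_k_curve: bool = False,
) -> dict[str, Path]:
    """Write modules, diagnostics and the score report for a pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for trace in result.traces:
        written = write_module(trace.module, out / trace.module.module_id)
        paths.update({f"{trace.module.module_id}_{k}": v for k, v in written.items()})
    curve_path = out / "cutoff_curve.tsv"
    write_cutoff_curve(result.curve, curve_path)
    paths["cutoff_curve"] = curve_path
    if result.scores:
        score_path = out / "score_report.tsv"
        write_score_report(result.scores, result.modules, score_path)
        paths["score_report"] = score_path
    if with_k_curve and result.traces:
        biggest = max(result.traces, key=lambda t: (len(t.cluster), min(t.cluster)))
        rows = k_curve(result.network, biggest.cluster, list(range(1, max(result.config.k, 10) + 1)))
        k_path = out / "k_curve.tsv"
        write_k_curve(rows, k_path)
        paths["k_curve"] = k_path
    resolved = out / "resolved_config.json"
    with resolved.open("w") as fh:
        payload = result.config.to_dict()
        payload["resolved_cutoff"] = result.cutoff
        payload["suggested_cutoff"] = result.suggested_cutoff
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["resolved_config"] = resolved
    return paths
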