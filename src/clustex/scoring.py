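"""Edge-based module scoring against a random-edge-sampling null.

The score of an edge (x, y) is escore = sd(x) * sd(y) * |cor(x, y)| — the
absolute sample covariance of the two expression series on the configured
scale — and the module score (mscore) is the sum of escores over the
module's edges.  Significance: draw the same number of distinct edges
uniformly from the whole network (10,000 times by default), and report
z = (mscore - null mean) / null sd.

The functional form of escore is injectable (``escore_fn``) like the edge
weight/distance functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError
from .expression import ExpressionStats
from .io_model import GeneNetwork, ResponsiveModule

EscoreFn = Callable[[ExpressionStats, str, str], float]


@dataclass
class ModuleScore:
    module_id: str
    mscore: float
    null_mean: float
    null_sd: float
    z_score: float
    n_samples: int
    seed: int


def escore(stats: ExpressionStats, x: str, y: str) -> float:
    """sd(x) * sd(y) * |cor(x, y)| = |sample covariance| of the two series."""
    return stats.sd(x) * stats.sd(y) * stats.abs_corr(x, y)


def _edge_scores(
    stats: ExpressionStats,
    pairs: list[tuple[str, str]],
    escore_fn: EscoreFn | None,
) -> np.ndarray:
    if escore_fn is None:
        return stats.covariance_edges(pairs)
    return np.array([escore_fn(stats, u, v) for u, v in pairs], dtype=float)


def mscore(
    module: ResponsiveModule,
    stats: ExpressionStats,
    escore_fn: EscoreFn | None = None,
) -> float:
    """Sum of escores over the module's edges (undefined for edgeless modules)."""
    if not module.edges:
        raise ConfigurationError(f"module {module.module_id} has no edges; mscore undefined")
    return float(_edge_scores(stats, list(module.edges), escore_fn).sum())


def _sample_subsets(rng: np.random.Generator, n_draws: int, pool: int, m: int) -> np.ndarray:
    """n_draws uniform m-subsets of range(pool), without replacement per draw.

    Selecting the indices of the m smallest of pool iid uniforms yields a
    uniformly random m-subset; argpartition keeps it O(pool) per draw.
    Chunked to bound memory.
    """
    out = np.empty((n_draws, m), dtype=np.int64)
    chunk = max(1, int(2e7) // max(pool, 1))
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        u = rng.random((stop - start, pool))
        out[start:stop] = np.argpartition(u, m, axis=1)[:, :m]
    return out


def module_zscore(
    module: ResponsiveModule,
    network: GeneNetwork,
    stats: ExpressionStats,
    n_samples: int = 10000,
    seed: int = 0,
    escore_fn: EscoreFn | None = None,
) -> ModuleScore:
    """Permutation z-score of the module score against random edge draws.

    Each of ``n_samples`` null scores sums the escores of |module edges|
    distinct edges sampled uniformly from the whole network.  Fully
    deterministic under ``seed``.
    """
    if n_samples < 2:
        raise ConfigurationError("n_samples must be >= 2")
    network_edges = network.edge_list()
    m = len(module.edges)
    if m == 0:
        raise ConfigurationError(f"module {module.module_id} has no edges")
    if m >= len(network_edges):
        raise ConfigurationError(
            "module covers the whole network edge set; null is degenerate"
        )
    observed = mscore(module, stats, escore_fn)
    scores = _edge_scores(stats, network_edges, escore_fn)

    rng = np.random.default_rng(seed)
    draws = _sample_subsets(rng, n_samples, len(network_edges), m)
    null_scores = scores[draws].sum(axis=1)
    null_mean = float(null_scores.mean())
    null_sd = float(null_scores.std(ddof=1))
    if null_sd == 0.0:
        raise ConfigurationError("null distribution has zero spread; z undefined")
    return ModuleScore(
        module_id=module.module_id,
        mscore=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=(observed - null_mean) / null_sd,
        n_samples=n_samples,
        seed=seed,
    )


def write_score_report(scores: list[ModuleScore], modules: list[ResponsiveModule], path) -> None:
    by_id = {m.module_id: m for m in modules}
    with open(path, "w") as fh:
        fh.write(
            "module_id\tn_genes\tn_edges\tmscore\tnull_mean\tnull_sd\tz_score\tn_samples\tseed\n"
        )
        for s in scores:
            mod = by_id[s.module_id]
            fh.write(
                f"{s.module_id}\t{mod.size}\t{len(mod.edges)}\t{s.mscore:.6g}\t"
                f"{s.null_mean:.6g}\t{s.null_sd:.6g}\t{s.z_score:.6g}\t{s.n_samples}\t{s.seed}\n"
            )
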