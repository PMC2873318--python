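"""Gene-set analysis of responsive modules.

Pathways and GO terms are scored by the Meet/Min overlap statistic
|A∩B| / min(|A|, |B|); miRNA target sets by the tscore — the sum of
network-based gene importance scores (gscores) over the overlap.  The
gscore of a module gene combines its expression change, its co-expression
with module neighbors and its module degree:

    gscore(x) = log2(max fold change of x) * sum over module neighbors y of |cor(x, y)|

Significance comes from degree-preserving permutations: each gene of the
tested set is replaced by a uniformly chosen gene from the same
network-degree bin (log2-width bins: degrees {1}, {2,3}, {4..7}, {8..15},
...), sampling without replacement within a permutation; 1,000 permutations
by default.  Enrichment is declared at z > 3.0 for Meet/Min (pathways/GO)
and z > 2.0 for tscores (miRNA targets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError
from .expression import ExpressionStats
from .io_model import GeneNetwork, GeneSetCollection, ResponsiveModule

DEFAULT_Z_CUTOFFS = {"meet_min": 3.0, "tscore": 2.0}

GscoreFn = Callable[[ExpressionStats, str, ResponsiveModule], float]


@dataclass
class EnrichmentResult:
    set_name: str
    statistic_kind: str  # "meet_min" | "tscore"
    statistic: float
    null_mean: float
    null_sd: float
    z_score: float
    n_perm: int
    enriched: bool
    evaluable: bool
    seed: int


def meet_min(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|a ∩ b| / min(|a|, |b|)."""
    if not a or not b:
        raise ConfigurationError("Meet/Min requires two non-empty sets")
    return len(set(a) & set(b)) / min(len(a), len(b))


def filter_gene_sets(
    collection: GeneSetCollection,
    min_size: int = 50,
    max_size: int = 500,
    universe: frozenset[str] | set[str] | None = None,
) -> GeneSetCollection:
    """Restrict sets to the analysis universe, then size-filter inclusively."""
    universe = frozenset(universe) if universe is not None else collection.universe
    if universe is None:
        raise ConfigurationError("filter_gene_sets requires a universe")
    kept: dict[str, frozenset[str]] = {}
    for name, members in collection.sets.items():
        restricted = members & universe
        if min_size <= len(restricted) <= max_size:
            kept[name] = restricted
    return GeneSetCollection(sets=kept, universe=universe)


def gscore(gene: str, module: ResponsiveModule, stats: ExpressionStats) -> float:
    """Importance of a module gene: log2(max fold) times Σ |cor| to module neighbors."""
    if gene not in module.genes:
        raise ConfigurationError(f"gene {gene!r} is not in module {module.module_id}")
    neighbors = [v if u == gene else u for u, v in module.edges if gene in (u, v)]
    corr_sum = sum(stats.abs_corr(gene, y) for y in neighbors)
    return float(np.log2(stats.max_fold(gene)) * corr_sum)


def gscore_table(module: ResponsiveModule, stats: ExpressionStats) -> dict[str, float]:
    return {g: gscore(g, module, stats) for g in sorted(module.genes)}


def tscore(
    module: ResponsiveModule,
    target_set: frozenset[str] | set[str],
    gscores: dict[str, float],
) -> float:
    """Sum of gscores over the module ∩ target-set overlap."""
    missing = module.genes - set(gscores)
    if missing:
        raise ConfigurationError(f"gscores missing for module genes {sorted(missing)[:3]}...")
    return float(sum(gscores[g] for g in module.genes & set(target_set)))


class DegreePreservingSampler:
    """Degree-binned gene permutation sampler over an analysis universe.

    Bins are log2-width in network degree (degree d goes to bin
    floor(log2(d)), degree-0 genes form their own bin), so heavy-tailed PPI
    degree distributions keep populated tail bins.
    """

    def __init__(self, network: GeneNetwork, universe: frozenset[str] | set[str]):
        universe = frozenset(universe)
        outside = universe - set(network.graph.nodes())
        if outside:
            raise ConfigurationError(
                f"universe genes missing from network, e.g. {sorted(outside)[:3]}"
            )
        self.universe = universe
        self._bin_of: dict[str, int] = {}
        bins: dict[int, list[str]] = {}
        for gene in sorted(universe):
            d = network.degree(gene)
            b = -1 if d == 0 else int(np.floor(np.log2(d)))
            self._bin_of[gene] = b
            bins.setdefault(b, []).append(gene)
        self._bins = {b: np.array(genes, dtype=object) for b, genes in bins.items()}

    def _grouped(self, observed: frozenset[str] | set[str]) -> dict[int, list[str]]:
        observed = set(observed)
        outside = observed - self.universe
        if outside:
            warnings.warn(
                f"{len(outside)} observed genes outside the universe were dropped"
            )
            observed -= outside
        if not observed:
            raise ConfigurationError("observed set empty after universe restriction")
        grouped: dict[int, list[str]] = {}
        for gene in sorted(observed):
            grouped.setdefault(self._bin_of[gene], []).append(gene)
        for b, members in grouped.items():
            if len(self._bins[b]) == 1:
                warnings.warn(
                    f"degree bin {b} holds a single gene; it maps to itself"
                )
        return grouped

    def sample_sets(
        self, observed: frozenset[str] | set[str], n: int, rng: np.random.Generator
    ) -> list[frozenset[str]]:
        """n degree-preserving permutations of the observed set (same size)."""
        grouped = self._grouped(observed)
        draws: list[set[str]] = [set() for _ in range(n)]
        for b, members in grouped.items():
            pool = self._bins[b]
            k = len(members)
            for i in range(n):
                idx = rng.choice(len(pool), size=k, replace=False)
                draws[i].update(pool[idx])
        return [frozenset(d) for d in draws]

    def null_value_sums(
        self,
        observed: frozenset[str] | set[str],
        values: dict[str, float],
        n: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Vectorized Σ values over each of n permuted sets.

        ``values`` maps universe genes to their contribution (0 for absent
        genes); only per-bin value vectors are materialized.
        """
        grouped = self._grouped(observed)
        totals = np.zeros(n)
        for b, members in grouped.items():
            pool = self._bins[b]
            k = len(members)
            vals = np.array([values.get(g, 0.0) for g in pool])
            if k == len(pool):
                totals += vals.sum()
                continue
            chunk = max(1, int(2e7) // max(len(pool), 1))
            for start in range(0, n, chunk):
                stop = min(start + chunk, n)
                u = rng.random((stop - start, len(pool)))
                picks = np.argpartition(u, k, axis=1)[:, :k]
                totals[start:stop] += vals[picks].sum(axis=1)
        return totals


def enrich(
    module: ResponsiveModule,
    collection: GeneSetCollection,
    network: GeneNetwork,
    kind: str = "meet_min",
    stats: ExpressionStats | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    z_cutoff: float | None = None,
    universe: frozenset[str] | set[str] | None = None,
) -> list[EnrichmentResult]:
    """Permutation enrichment of every set in the collection against a module.

    ``kind`` selects Meet/Min (pathways/GO) or tscore (miRNA target sets; the
    latter needs ``stats`` for gscores).  For each set, ``n_perm``
    degree-preserving permutations build the null; results come back sorted
    by z descending with non-evaluable sets (zero null spread) last.
    """
    if kind not in DEFAULT_Z_CUTOFFS:
        raise ConfigurationError(f"unknown enrichment kind {kind!r}")
    cutoff = DEFAULT_Z_CUTOFFS[kind] if z_cutoff is None else z_cutoff
    universe = frozenset(universe) if universe is not None else (
        collection.universe or frozenset(network.graph.nodes())
    )
    sampler = DegreePreservingSampler(network, universe)

    module_genes = module.genes & universe
    if kind == "tscore":
        if stats is None:
            raise ConfigurationError("tscore enrichment requires expression statistics")
        gscores = gscore_table(module, stats)
        values = {g: gscores[g] for g in module_genes}
    else:
        values = {g: 1.0 for g in module_genes}

    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    for name in collection.names():
        members = collection.sets[name] & universe
        if not members:
            warnings.warn(f"gene set {name!r} has no genes in the universe; skipped")
            continue
        if kind == "meet_min":
            denom = min(len(members), len(module_genes))
            observed = len(members & module_genes) / denom
            null = sampler.null_value_sums(members, values, n_perm, rng) / denom
        else:
            observed = float(sum(values.get(g, 0.0) for g in members))
            null = sampler.null_value_sums(members, values, n_perm, rng)
        null_mean = float(null.mean())
        null_sd = float(null.std(ddof=1))
        evaluable = null_sd > 0.0
        z = (observed - null_mean) / null_sd if evaluable else float("nan")
        results.append(
            EnrichmentResult(
                set_name=name,
                statistic_kind=kind,
                statistic=float(observed),
                null_mean=null_mean,
                null_sd=null_sd,
                z_score=z,
                n_perm=n_perm,
                enriched=bool(evaluable and z > cutoff),
                evaluable=evaluable,
                seed=seed,
            )
        )
    results.sort(
        key=lambda r: (not r.evaluable, -r.z_score if r.evaluable else 0.0, r.set_name)
    )
    return results


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("set_name\tkind\tobserved\tnull_mean\tnull_sd\tz\tenriched\tn_perm\tseed\n")
        for r in results:
            z = f"{r.z_score:.6g}" if r.evaluable else "NA"
            fh.write(
                f"{r.set_name}\t{r.statistic_kind}\t{r.statistic:.6g}\t{r.null_mean:.6g}\t"
                f"{r.null_sd:.6g}\t{z}\t{int(r.enriched)}\t{r.n_perm}\t{r.seed}\n"
            )
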