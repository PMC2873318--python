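"""Per-gene expression statistics: fold changes, DE selection, correlation.

DE genes are called by the maximum fold change over the time course relative
to the baseline (0 h) column, computed on the raw non-log signal scale, in
either direction.  Correlations and standard deviations — the ingredients of
edge weights and edge scores — are computed by default on log2-transformed
signals (with a configurable raw-scale option), because log transformation
stabilizes Pearson correlation against the magnitude outliers typical of
microarray signal values; the scale choice is recorded in run metadata.

A floor ``eps`` (default 1.0 on the raw signal scale) protects ratios and
logs against zero signals, which are noise-dominated on arrays anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .io_model import ExpressionMatrix

DEFAULT_EPS = 1.0


@dataclass
class GeneExpressionStats:
    gene_id: str
    max_fold_change: float
    direction: str  # "up" | "down"
    sd: float
    series: np.ndarray


def max_fold_change(
    series: np.ndarray, baseline_index: int, eps: float = DEFAULT_EPS
) -> tuple[float, str]:
    """Maximum fold change of a signal series relative to its baseline entry.

    For each non-baseline time point t the fold is max(s_t/s_0, s_0/s_t) after
    flooring signals at ``eps``; the maximum over t is returned together with
    the direction of the maximizing ratio ("up" if s_t/s_0 attains it).
    A constant (or all-zero) series yields (1.0, "up").
    """
    s = np.maximum(np.asarray(series, dtype=float), eps)
    if not (0 <= baseline_index < s.size):
        raise ConfigurationError(f"baseline index {baseline_index} out of range")
    ratios = s / s[baseline_index]
    folds = np.maximum(ratios, 1.0 / ratios)
    folds[baseline_index] = 1.0
    t = int(np.argmax(folds))
    fold = float(folds[t])
    direction = "up" if ratios[t] >= 1.0 else "down"
    return fold, direction


def select_de_genes(
    matrix: ExpressionMatrix, min_fold: float = 2.0, eps: float = DEFAULT_EPS
) -> frozenset[str]:
    """Genes whose maximum fold change reaches ``min_fold`` (inclusive)."""
    if min_fold < 1.0:
        raise ConfigurationError(f"min_fold must be >= 1, got {min_fold}")
    if matrix.has_duplicate_genes():
        raise ConfigurationError("collapse probes before DE selection")
    s = np.maximum(matrix.signals, eps)
    ratios = s / s[:, [matrix.baseline_index]]
    folds = np.maximum(ratios, 1.0 / ratios)
    folds[:, matrix.baseline_index] = 1.0
    keep = folds.max(axis=1) >= min_fold
    genes = matrix.gene_ids
    return frozenset(g for g, k in zip(genes, keep) if k)


def abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson correlation| of two equal-length vectors; 0 if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("abs_pearson requires two equal-length vectors")
    if x.size < 2:
        raise ConfigurationError("abs_pearson requires length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(xc @ xc))
    ny = float(np.sqrt(yc @ yc))
    if nx == 0.0 or ny == 0.0:
        return 0.0
    r = float(xc @ yc) / (nx * ny)
    return min(abs(r), 1.0)


def series_sd(x: np.ndarray) -> float:
    """Sample standard deviation (ddof=1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ConfigurationError("series_sd requires length >= 2")
    return float(np.std(x, ddof=1))


class ExpressionStats:
    """Vectorized per-gene statistics over a collapsed expression matrix.

    Holds fold changes/directions (raw scale) plus the centered signal matrix
    on the configured correlation scale, so that correlations, standard
    deviations and edge scores come from cheap dot products.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        scale: str = "log2",
        eps: float = DEFAULT_EPS,
    ) -> None:
        if matrix.has_duplicate_genes():
            raise ConfigurationError("collapse probes before computing statistics")
        if scale not in ("log2", "raw"):
            raise ConfigurationError(f"unknown correlation scale {scale!r}")
        self.scale = scale
        self.eps = eps
        self.gene_ids = matrix.gene_ids
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        raw = np.maximum(matrix.signals, eps)

        ratios = raw / raw[:, [matrix.baseline_index]]
        folds = np.maximum(ratios, 1.0 / ratios)
        folds[:, matrix.baseline_index] = 1.0
        t = np.argmax(folds, axis=1)
        rows = np.arange(raw.shape[0])
        self.folds = folds[rows, t]
        self.directions = np.where(ratios[rows, t] >= 1.0, "up", "down")

        X = np.log2(raw) if scale == "log2" else raw
        self._X = X
        self._centered = X - X.mean(axis=1, keepdims=True)
        n = X.shape[1]
        self._n_samples = n
        self.sds = np.sqrt((self._centered**2).sum(axis=1) / (n - 1))
        norms = np.sqrt((self._centered**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            self._unit = np.where(norms[:, None] > 0, self._centered / norms[:, None], 0.0)

    # -- per-gene accessors ---------------------------------------------------
    def has(self, gene: str) -> bool:
        return gene in self._index

    def _i(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise ConfigurationError(f"gene {gene!r} has no expression data") from None

    def max_fold(self, gene: str) -> float:
        return float(self.folds[self._i(gene)])

    def direction(self, gene: str) -> str:
        return str(self.directions[self._i(gene)])

    def sd(self, gene: str) -> float:
        return float(self.sds[self._i(gene)])

    def series(self, gene: str) -> np.ndarray:
        return self._X[self._i(gene)].copy()

    def abs_corr(self, x: str, y: str) -> float:
        r = float(self._unit[self._i(x)] @ self._unit[self._i(y)])
        return min(abs(r), 1.0)

    def stats_for(self, gene: str) -> GeneExpressionStats:
        i = self._i(gene)
        return GeneExpressionStats(
            gene_id=gene,
            max_fold_change=float(self.folds[i]),
            direction=str(self.directions[i]),
            sd=float(self.sds[i]),
            series=self._X[i].copy(),
        )

    # -- vectorized edge helpers ---------------------------------------------
    def abs_corr_edges(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        """|cor| for a list of gene pairs in one shot."""
        if not pairs:
            return np.empty(0)
        i = np.array([self._i(u) for u, _ in pairs])
        j = np.array([self._i(v) for _, v in pairs])
        r = np.einsum("ij,ij->i", self._unit[i], self._unit[j])
        return np.minimum(np.abs(r), 1.0)

    def covariance_edges(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        """|sample covariance| per pair — equals sd(x)*sd(y)*|cor(x,y)|."""
        if not pairs:
            return np.empty(0)
        i = np.array([self._i(u) for u, _ in pairs])
        j = np.array([self._i(v) for _, v in pairs])
        cov = np.einsum("ij,ij->i", self._centered[i], self._centered[j])
        return np.abs(cov) / (self._n_samples - 1)
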