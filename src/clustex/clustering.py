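"""Average-linkage clustering of DE genes on network distances.

The DE genes are agglomerated on their shortest-path distance matrix
(UPGMA-style average linkage).  Pairs at infinite distance — genes in
different network components — never merge, so the result is a forest with
one dendrogram per finite-distance component.  A distance cutoff partitions
the dendrogram into separate DE gene groups; the cutoff is chosen from the
growth curve of the biggest group (size vs cutoff), at the point where the
expansion decelerates sharply.

Determinism: when two candidate merges have exactly the same average
distance, the pair whose lexicographically smallest member is smallest wins
(then the smaller partner cluster).
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .graph import DistanceMatrix


@dataclass(frozen=True)
class Merge:
    a: tuple[str, ...]
    b: tuple[str, ...]
    height: float

    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.a + self.b))


@dataclass
class Dendrogram:
    leaves: list[str]
    merges: list[Merge]


@dataclass
class ClusterPartition:
    clusters: list[tuple[str, ...]]
    cutoff: float

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration of the given distance matrix.

    Cluster-to-cluster distances follow the Lance-Williams average-linkage
    update d(k, i+j) = (n_i d(k,i) + n_j d(k,j)) / (n_i + n_j); infinite
    entries propagate, so cross-component merges never occur.  Merge heights
    are non-decreasing (average linkage is monotone).
    """
    leaves = list(dist.gene_ids)
    n = len(leaves)
    if n < 2:
        return Dendrogram(leaves=leaves, merges=[])
    if not np.allclose(np.diag(dist.d), 0.0):
        raise ConfigurationError("distance matrix must have a zero diagonal")

    D = dist.d.astype(float).copy()
    if np.isnan(D).any() or (D[np.isfinite(D)] < 0).any():
        raise ConfigurationError("distances must be non-negative (inf allowed, NaN not)")
    np.fill_diagonal(D, np.inf)

    members: dict[int, tuple[str, ...]] = {i: (leaves[i],) for i in range(n)}
    sizes = np.ones(n)
    merges: list[Merge] = []

    while True:
        height = D.min()
        if not np.isfinite(height):
            break
        ii, jj = np.where(D == height)
        # candidates as (i, j) with i < j; pick deterministic winner
        best: tuple[tuple[str, str], int, int] | None = None
        for i, j in zip(ii, jj):
            if i >= j:
                continue
            key = tuple(sorted((members[i][0], members[j][0])))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        assert best is not None
        _, i, j = best
        a, b = sorted((members[i], members[j]))
        merges.append(Merge(a=a, b=b, height=float(height)))

        ni, nj = sizes[i], sizes[j]
        row = (ni * D[i, :] + nj * D[j, :]) / (ni + nj)
        D[i, :] = row
        D[:, i] = row
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        members[i] = tuple(sorted(members[i] + members[j]))
        del members[j]
        sizes[i] = ni + nj
    return Dendrogram(leaves=leaves, merges=merges)


def partition_at_cutoff(dend: Dendrogram, cutoff: float) -> ClusterPartition:
    """Cut the dendrogram: apply every merge with height <= cutoff (inclusive).

    Clusters come back sorted by size descending, ties broken by the
    lexicographically smallest member.
    """
    if cutoff < 0:
        raise ConfigurationError(f"cutoff must be >= 0, got {cutoff}")
    parent: dict[str, str] = {g: g for g in dend.leaves}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for merge in dend.merges:
        if merge.height <= cutoff:
            ra, rb = find(merge.a[0]), find(merge.b[0])
            if ra != rb:
                parent[rb] = ra
    groups: dict[str, list[str]] = {}
    for g in dend.leaves:
        groups.setdefault(find(g), []).append(g)
    clusters = sorted(
        (tuple(sorted(v)) for v in groups.values()),
        key=lambda c: (-len(c), c[0]),
    )
    return ClusterPartition(clusters=clusters, cutoff=float(cutoff))


def cutoff_curve(dend: Dendrogram, grid: list[float]) -> list[tuple[float, int]]:
    """Size of the biggest cluster at each cutoff of an ascending grid."""
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ConfigurationError("cutoff grid must be sorted ascending")
    sizes: dict[str, int] = {g: 1 for g in dend.leaves}
    rep: dict[str, str] = {g: g for g in dend.leaves}

    def find(g: str) -> str:
        while rep[g] != g:
            rep[g] = rep[rep[g]]
            g = rep[g]
        return g

    heights: list[float] = []
    biggest_after: list[int] = []
    biggest = 1 if dend.leaves else 0
    for merge in dend.merges:
        ra, rb = find(merge.a[0]), find(merge.b[0])
        rep[rb] = ra
        sizes[ra] = sizes[ra] + sizes[rb]
        biggest = max(biggest, sizes[ra])
        heights.append(merge.height)
        biggest_after.append(biggest)

    base = 1 if dend.leaves else 0
    curve = []
    for c in grid:
        idx = bisect_right(heights, c)
        curve.append((float(c), biggest_after[idx - 1] if idx else base))
    return curve


def default_grid(dend: Dendrogram, n_steps: int = 100) -> list[float]:
    """0 to the maximum finite merge height in ``n_steps`` equal steps."""
    top = max((m.height for m in dend.merges), default=0.0)
    if top <= 0:
        return [0.0]
    # last grid point must equal the top height exactly (inclusive partition)
    return [top * i / n_steps for i in range(n_steps)] + [top]


def _chord_deviation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vertical distance of the axis-normalized curve above its end-to-end chord."""
    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (y - y.min()) / (y.max() - y.min())
    return yn - (yn[0] + (yn[-1] - yn[0]) * xn)


def suggest_cutoff(
    curve: list[tuple[float, int]],
    min_knee_deviation: float = 0.15,
) -> float:
    """Advisory cutoff from the biggest-cluster growth curve.

    For a concave curve (fast growth, then decisively slower) the knee is
    the grid point of maximum vertical distance above the chord joining the
    curve's endpoints, axes normalized to [0, 1] — the point after which
    expansion slows.  Curves on network distances are often convex instead
    — gradual consolidation ending in the coalescence of whole gene groups
    — and have no such knee (maximum deviation below
    ``min_knee_deviation``); the smallest grid point attaining the maximal
    size is then returned, i.e. the single-dominant-group regime, with a
    warning when the curve is entirely flat.  Advisory only: the CLI never
    applies it without confirmation.
    """
    if len(curve) < 3:
        raise ConfigurationError("cutoff curve needs at least 3 points")
    x = np.array([c for c, _ in curve], dtype=float)
    y = np.array([s for _, s in curve], dtype=float)

    def fallback() -> float:
        return float(x[int(np.argmax(y == y.max()))])

    if y.max() == y.min() or x.max() == x.min():
        warnings.warn("flat cutoff curve; returning smallest cutoff with maximal size")
        return fallback()

    deviation = _chord_deviation(x, y)
    if deviation.max() >= min_knee_deviation:
        return float(x[int(np.argmax(deviation))])
    warnings.warn(
        "no pronounced knee in the cutoff curve; returning the smallest cutoff "
        "attaining the maximal cluster size"
    )
    return fallback()


def write_cutoff_curve(curve: list[tuple[float, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("cutoff\tbiggest_cluster_size\n")
        for c, s in curve:
            fh.write(f"{c:.6g}\t{s}\n")
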