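"""Readers/writers for the external formats and the shared in-memory data model.

The pipeline exchanges four kinds of objects between stages:

* :class:`ExpressionMatrix` — a genes x time-points table of non-log microarray
  signal values with a designated baseline (0 h) column;
* :class:`GeneNetwork` — an undirected simple graph over gene identifiers,
  optionally carrying per-edge ``weight`` (|Pearson correlation|) and
  ``distance`` attributes;
* :class:`GeneSetCollection` — named gene sets (pathways, GO terms, miRNA
  targets) as read from GMT files;
* :class:`ResponsiveModule` — an identified module: genes, their provenance
  (DE seed / shortest-path intermediate / k-shortest-path intermediate) and
  the edges extracted with them.

Gene identifiers are opaque case-sensitive strings throughout; no symbol/ID
mapping is attempted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

PROVENANCE_CLASSES = ("de", "shortest_path", "k_shortest")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x time-points signal matrix (non-log scale) with a baseline column.

    ``df`` is indexed by gene identifier (duplicates allowed until
    :func:`collapse_probes` is applied) with one column per sample label.
    """

    df: pd.DataFrame
    baseline_index: int

    def __post_init__(self) -> None:
        if self.df.shape[1] < 2:
            raise FormatError("expression matrix needs at least 2 time points")
        labels = list(self.df.columns)
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate sample labels in expression matrix")
        if not (0 <= self.baseline_index < self.df.shape[1]):
            raise ConfigurationError(
                f"baseline index {self.baseline_index} outside 0..{self.df.shape[1] - 1}"
            )
        values = self.df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise FormatError("expression signals must be finite")
        if (values < 0).any():
            raise FormatError("expression signals must be non-negative")

    # -- convenience accessors ------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.df.index]

    @property
    def time_labels(self) -> list[str]:
        return [str(c) for c in self.df.columns]

    @property
    def baseline_label(self) -> str:
        return str(self.df.columns[self.baseline_index])

    @property
    def signals(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.df.shape[0]

    def has_duplicate_genes(self) -> bool:
        return bool(self.df.index.duplicated().any())

    def series(self, gene: str) -> np.ndarray:
        if self.has_duplicate_genes():
            raise ConfigurationError("collapse probes before per-gene access")
        return self.df.loc[gene].to_numpy(dtype=float)


def read_expression(path: str | Path, baseline_label: str) -> ExpressionMatrix:
    """Read a TSV expression table (header = sample labels, column 1 = gene id).

    Rows containing any non-numeric cell are dropped with a warning.  Duplicate
    gene rows are kept; resolve them with :func:`collapse_probes`.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty expression file")
        cols = header.rstrip("\n").split("\t")
        sample_labels = cols[1:]
        if len(sample_labels) != len(set(sample_labels)):
            raise FormatError(f"{path}: duplicate sample labels in header")
        if baseline_label not in sample_labels:
            raise ConfigurationError(
                f"baseline label {baseline_label!r} not found among samples {sample_labels}"
            )
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(cols):
                raise FormatError(f"{path}:{lineno}: expected {len(cols)} columns, got {len(cells)}")
            try:
                values = [float(c) for c in cells[1:]]
            except ValueError:
                warnings.warn(f"{path}:{lineno}: non-numeric cell, row {cells[0]!r} dropped")
                continue
            genes.append(cells[0])
            rows.append(values)
    df = pd.DataFrame(rows, index=genes, columns=sample_labels, dtype=float)
    return ExpressionMatrix(df, sample_labels.index(baseline_label))


def collapse_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse repeated gene rows to their column-wise arithmetic mean.

    Averaging is done on the raw (non-log) signal scale.  Row order follows the
    first occurrence of each gene.
    """
    if not matrix.has_duplicate_genes():
        return ExpressionMatrix(matrix.df.copy(), matrix.baseline_index)
    collapsed = matrix.df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(collapsed, matrix.baseline_index)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


# ---------------------------------------------------------------------------
# Gene network
# ---------------------------------------------------------------------------

@dataclass
class GeneNetwork:
    """Undirected simple gene graph, optionally weighted.

    Edge attributes, when present: ``weight`` = |Pearson correlation| in [0, 1]
    and ``distance`` >= 0 (small distance = strong co-expression).
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges()):
            raise FormatError("gene network must not contain self-loops")
        for u, v, data in self.graph.edges(data=True):
            w = data.get("weight")
            if w is not None and not (0.0 <= w <= 1.0):
                raise FormatError(f"edge ({u},{v}) weight {w} outside [0,1]")
            d = data.get("distance")
            if d is not None and not (np.isfinite(d) and d >= 0.0):
                raise FormatError(f"edge ({u},{v}) distance {d} not finite/non-negative")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "GeneNetwork":
        g = nx.Graph()
        for u, v in edges:
            if u != v:
                g.add_edge(u, v)
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_list(self) -> list[str]:
        return sorted(self.graph.nodes())

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges())

    def has_node(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def subgraph(self, nodes: Iterable[str]) -> "GeneNetwork":
        return GeneNetwork(self.graph.subgraph(nodes).copy())

    def degree(self, gene: str) -> int:
        return int(self.graph.degree[gene])


def read_network(path: str | Path) -> GeneNetwork:
    """Read an edge list: 2-column TSV ("A  B") or 3-column SIF ("A pp B").

    The relation token of SIF lines is ignored.  Self-loops are dropped,
    duplicate and reversed-duplicate edges are merged.
    """
    path = Path(path)
    g = nx.Graph()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) == 2:
                u, v = tokens
            elif len(tokens) == 3:
                u, _, v = tokens
            else:
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(tokens)}")
            if u == v:
                continue
            g.add_edge(u, v)
    return GeneNetwork(g)


def write_network(network: GeneNetwork, path: str | Path, relation: str = "pp") -> None:
    with Path(path).open("w") as fh:
        for u, v in network.edge_list():
            fh.write(f"{u}\t{relation}\t{v}\n")


# ---------------------------------------------------------------------------
# Gene set collections (GMT) and plain gene lists
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def names(self) -> list[str]:
        return sorted(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then members (tabs)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name = cells[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = frozenset(c for c in cells[2:] if c)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in collection.names():
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t-\t{members}\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a reference gene list, one identifier per line."""
    genes = set()
    with Path(path).open() as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                genes.add(token)
    return frozenset(genes)


# ---------------------------------------------------------------------------
# Responsive modules
# ---------------------------------------------------------------------------

@dataclass
class ResponsiveModule:
    """An identified responsive gene module.

    ``provenance`` labels every gene as a clustered DE seed (``de``), an
    intermediate on a plain shortest path (``shortest_path``) or an
    intermediate recovered only on 2nd..k-th shortest paths (``k_shortest``).
    """

    module_id: str
    genes: frozenset[str]
    de_genes: frozenset[str]
    provenance: dict[str, str]
    edges: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.de_genes <= self.genes:
            raise ConfigurationError("de_genes must be a subset of module genes")
        if set(self.provenance) != set(self.genes):
            raise ConfigurationError("provenance must label every module gene exactly")
        bad = set(self.provenance.values()) - set(PROVENANCE_CLASSES)
        if bad:
            raise ConfigurationError(f"unknown provenance labels: {sorted(bad)}")
        for u, v in self.edges:
            if u not in self.genes or v not in self.genes:
                raise ConfigurationError(f"edge ({u},{v}) endpoint outside module genes")

    @property
    def size(self) -> int:
        return len(self.genes)

    def provenance_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in PROVENANCE_CLASSES}
        for label in self.provenance.values():
            counts[label] += 1
        return counts


def write_module(module: ResponsiveModule, out_prefix: str | Path) -> dict[str, Path]:
    """Write a module as gene table TSV + edge SIF + JSON summary.

    Returns the mapping of artifact kind to path.  Empty modules are rejected.
    """
    if not module.genes:
        raise ConfigurationError("cannot write an empty module")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    gene_path = prefix.with_name(prefix.name + "_genes.tsv")
    edge_path = prefix.with_name(prefix.name + "_edges.sif")
    summary_path = prefix.with_name(prefix.name + "_summary.json")

    with gene_path.open("w") as fh:
        fh.write("gene\tprovenance\tis_de\n")
        for gene in sorted(module.genes):
            is_de = "1" if gene in module.de_genes else "0"
            fh.write(f"{gene}\t{module.provenance[gene]}\t{is_de}\n")

    with edge_path.open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in module.edges):
            fh.write(f"{u}\tpp\t{v}\n")

    summary = {
        "module_id": module.module_id,
        "n_genes": module.size,
        "n_de_genes": len(module.de_genes),
        "n_edges": len(module.edges),
        "provenance_counts": module.provenance_counts(),
    }
    with summary_path.open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"genes": gene_path, "edges": edge_path, "summary": summary_path}


def read_module_genes(path: str | Path) -> ResponsiveModule:
    """Re-read a gene table written by :func:`write_module` (round-trip)."""
    path = Path(path)
    provenance: dict[str, str] = {}
    de: set[str] = set()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene", "provenance", "is_de"]:
            raise FormatError(f"{path}: not a module gene table")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            gene, label, is_de = cells
            provenance[gene] = label
            if is_de == "1":
                de.add(gene)
    module_id = path.name.removesuffix("_genes.tsv")
    return ResponsiveModule(
        module_id=module_id,
        genes=frozenset(provenance),
        de_genes=frozenset(de),
        provenance=provenance,
    )
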