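"""Expression-matrix and gene-network containers, file IO, imputation, normalization.

The expression matrix is genes x samples with unique string identifiers on
both axes.  The gene network is an undirected simple graph on gene IDs that
restricts which gene pairs are screened for differential co-expression.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneNetwork",
    "Bicluster",
    "ParseError",
    "ValidationError",
    "read_expression_table",
    "write_expression_table",
    "knn_impute",
    "normalize_per_gene",
    "read_edge_list",
    "write_edge_list",
    "prune_isolated_genes",
    "write_biclusters_tsv",
    "read_biclusters_tsv",
    "write_biclusters_json",
]

#: strings accepted as missing values in input tables (besides empty cells)
NA_VALUES = ["", "NA", "NaN", "nan", "na"]


class ParseError(ValueError):
    """A file could not be parsed into the expected tabular shape."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant (e.g. duplicate IDs)."""


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with ID labels.

    ``values[g, s]`` is the expression of gene ``gene_ids[g]`` in sample
    ``sample_ids[s]``.  Missing entries (NaN) are allowed before imputation
    and forbidden afterwards.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene IDs: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample IDs: {sorted(dupes)[:5]}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def sample_indices(self, samples: Iterable[str]) -> np.ndarray:
        try:
            return np.asarray(sorted(self._sample_index[s] for s in samples), dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        idx = [self._gene_index[g] for g in keep]
        return ExpressionMatrix(keep, list(self.sample_ids), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class GeneNetwork:
    """Undirected simple graph on gene identifiers (no self-loops)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "GeneNetwork":
        g = nx.Graph()
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                logger.warning("dropping self-loop on %r", a)
                continue
            g.add_edge(a, b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        # canonical order: endpoints sorted within the pair, pairs sorted
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def connected_component_labels(self) -> dict[frozenset, int]:
        """Map each edge (as a frozenset pair) to a component index."""
        comp_of_node: dict[str, int] = {}
        for k, comp in enumerate(nx.connected_components(self.graph)):
            for node in comp:
                comp_of_node[node] = k
        return {frozenset(e): comp_of_node[e[0]] for e in self.graph.edges}


@dataclass(frozen=True)
class Bicluster:
    """A gene set co-behaving on a sample subset, with its average SNR."""

    genes: frozenset[str]
    samples: frozenset[str]
    avg_snr: float = 0.0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("bicluster with empty gene set")
        if not self.samples:
            raise ValidationError("bicluster with empty sample set")


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        (dup if it in seen else seen).add(it)
    return dup


# ---------------------------------------------------------------------------
# expression tables


def _sniff_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    delimiter: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression table.

    The first column holds gene IDs and the header row sample IDs; with
    ``transpose=True`` the file is samples x genes and is transposed on read.
    Empty cells, ``NA`` and ``NaN`` are treated as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            na_values=NA_VALUES,
            keep_default_na=False,
            dtype=str,
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell: {exc}") from exc
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        raise ValidationError(
            f"{path}: duplicate gene IDs: "
            f"{sorted(df.index[df.index.duplicated()].unique())[:5]}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix.from_frame(df)


def write_expression_table(m: ExpressionMatrix, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    m.to_frame().to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# imputation / normalization


def knn_impute(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute missing entries from the k nearest genes.

    Distances between genes are Euclidean over co-observed samples, scaled
    by the fraction of co-observed samples; each missing cell becomes the
    mean of the k nearest genes' values in that sample.  A no-op on complete
    matrices.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nan_mask = np.isnan(m.values)
    if not nan_mask.any():
        return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), m.values.copy())
    all_missing = nan_mask.all(axis=1)
    if all_missing.any():
        bad = [m.gene_ids[i] for i in np.where(all_missing)[0]]
        raise ValidationError(f"genes missing in every sample, cannot impute: {bad[:5]}")
    n_complete = int((~nan_mask.any(axis=1)).sum())
    if k > n_complete:
        raise ValidationError(
            f"k={k} exceeds the number of complete genes ({n_complete})"
        )
    from sklearn.impute import KNNImputer

    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    # genes are observations (rows), samples are features
    filled = imputer.fit_transform(m.values)
    if filled.shape != m.values.shape:  # a fully-missing column was dropped
        raise ValidationError("a sample column has no observed values at all")
    out = m.values.copy()
    out[nan_mask] = filled[nan_mask]
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), out)


def normalize_per_gene(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row (population SD).  Constant rows become all-zero.

    Constant genes can never show a between-sample-set mean difference, so
    mapping them to zero rather than erroring keeps them harmlessly inert in
    downstream SNR screening.
    """
    if np.isnan(m.values).any():
        raise ValidationError("normalize_per_gene requires a complete matrix; impute first")
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=0, keepdims=True)
    out = np.zeros_like(m.values)
    ok = (sd > 0).ravel()
    out[ok] = (m.values[ok] - mu[ok]) / sd[ok]
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), out)


# ---------------------------------------------------------------------------
# networks


def read_edge_list(path: str | Path) -> GeneNetwork:
    """Read a two-column edge list; extra columns (scores) are ignored.

    Duplicate edges are collapsed, self-loops dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise ParseError(f"{path}:{ln}: expected at least two columns")
            edges.append((parts[0], parts[1]))
    if not edges:
        warnings.warn(f"{path}: empty edge list")
    return GeneNetwork.from_edges(edges)


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in net.edges:
            fh.write(f"{a}\t{b}\n")


def prune_isolated_genes(
    net: GeneNetwork, m: ExpressionMatrix
) -> tuple[GeneNetwork, ExpressionMatrix]:
    """Intersect network and matrix gene universes and drop degree-0 genes.

    Genes without any interaction partner cannot take part in edge screening
    and are discarded from both objects.
    """
    common = net.nodes & set(m.gene_ids)
    sub = net.graph.subgraph(common).copy()
    sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree(n) == 0])
    if sub.number_of_edges() == 0:
        raise ValidationError("no network edge has both endpoints in the matrix")
    kept = set(sub.nodes)
    dropped = m.n_genes - len(kept)
    logger.info("pruning: kept %d genes, dropped %d isolated/absent", len(kept), dropped)
    return GeneNetwork(sub), m.subset_genes(sorted(kept))


# ---------------------------------------------------------------------------
# bicluster output


def _sorted_join(ids: Iterable[str]) -> str:
    return ";".join(sorted(ids))


def write_biclusters_tsv(clusters: Sequence[Bicluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tavg_snr\tn_genes\tn_samples\tgene_ids\tsample_ids\n")
        for i, c in enumerate(clusters, start=1):
            fh.write(
                f"{i}\t{c.avg_snr:.9g}\t{len(c.genes)}\t{len(c.samples)}\t"
                f"{_sorted_join(c.genes)}\t{_sorted_join(c.samples)}\n"
            )


def read_biclusters_tsv(path: str | Path) -> list[Bicluster]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            Bicluster(
                genes=frozenset(row["gene_ids"].split(";")),
                samples=frozenset(row["sample_ids"].split(";")),
                avg_snr=float(row["avg_snr"]),
            )
        )
    return out


def write_biclusters_json(clusters: Sequence[Bicluster], path: str | Path) -> None:
    payload = [
        {
            "cluster_id": i,
            "avg_snr": c.avg_snr,
            "genes": sorted(c.genes),
            "samples": sorted(c.samples),
        }
        for i, c in enumerate(clusters, start=1)
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
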