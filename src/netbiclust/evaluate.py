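"""Jaccard scoring of recovered biclusters against planted ground truth.

Similarity is measured on (gene, sample) CELL sets: for biclusters A and B,
cells(A) = genes(A) x samples(A) and

    J(A, B) = |cells(A) ∩ cells(B)| / |cells(A) ∪ cells(B)|.

The headline number is *recovery*: the mean over true modules of the best
Jaccard achieved by any found cluster.  Its dual, *relevance* (mean over
found clusters of their best match), is reported alongside, plus per-size
group means for module-size breakdowns.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import Bicluster, ExpressionMatrix, read_biclusters_tsv
from .simulate import PlantedModule
from .snr import set_snr

__all__ = [
    "cell_jaccard",
    "recovery_score",
    "EvaluationReport",
    "import_external_result",
]

SetLike = Bicluster | PlantedModule


@dataclass
class EvaluationReport:
    per_module_best: list[float]
    recovery: float
    relevance: float
    by_gene_count: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "recovery": self.recovery,
            "relevance": self.relevance,
            "per_module_best": self.per_module_best,
            "by_gene_count": {str(k): v for k, v in self.by_gene_count.items()},
        }


def cell_jaccard(a: SetLike, b: SetLike) -> float:
    """Jaccard of the two (gene, sample) cell sets."""
    na = len(a.genes) * len(a.samples)
    nb = len(b.genes) * len(b.samples)
    if na == 0 and nb == 0:
        raise ValueError("both cell sets empty")
    inter = len(a.genes & b.genes) * len(a.samples & b.samples)
    return inter / (na + nb - inter)


def recovery_score(found: Sequence[SetLike], truth: Sequence[SetLike]) -> EvaluationReport:
    """Best-match Jaccard per true module, with recovery/relevance means."""
    if not truth:
        raise ValueError("empty ground truth")
    if not found:
        return EvaluationReport(
            [0.0] * len(truth), 0.0, 0.0,
            {len(t.genes): 0.0 for t in truth},
        )
    sim = np.array([[cell_jaccard(t, f) for f in found] for t in truth])
    per_true = sim.max(axis=1)
    per_found = sim.max(axis=0)
    groups: dict[int, list[float]] = {}
    for t, score in zip(truth, per_true):
        groups.setdefault(len(t.genes), []).append(float(score))
    return EvaluationReport(
        per_module_best=[float(v) for v in per_true],
        recovery=float(per_true.mean()),
        relevance=float(per_found.mean()),
        by_gene_count={k: float(np.mean(v)) for k, v in sorted(groups.items())},
    )


def import_external_result(
    path: str | Path,
    format: str = "bicluster-tsv",
    matrix: ExpressionMatrix | None = None,
    universe: tuple[set[str], set[str]] | None = None,
) -> list[Bicluster]:
    """Read clusters produced by this package or by an external tool.

    ``bicluster-tsv`` is this package's own output layout; ``triplet-list``
    is a loose ``cluster_id <TAB> gene <TAB> sample`` long format.  Average
    SNRs are recomputed when an expression matrix is supplied, else 0.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"{path}: empty result file")
        return []
    if format == "bicluster-tsv":
        clusters = read_biclusters_tsv(path)
    elif format == "triplet-list":
        groups: dict[str, tuple[set[str], set[str]]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if len(parts) != 3:
                    raise ValueError(f"{path}: expected 'cluster gene sample' triplets")
                cid, gene, sample = parts
                groups.setdefault(cid, (set(), set()))
                groups[cid][0].add(gene)
                groups[cid][1].add(sample)
        clusters = [
            Bicluster(frozenset(g), frozenset(s), 0.0) for g, s in groups.values()
        ]
    else:
        raise ValueError(f"unknown format {format!r}")
    if universe is None and matrix is not None:
        universe = (set(matrix.gene_ids), set(matrix.sample_ids))
    if universe is not None:
        gene_u, sample_u = universe
        bad_g = sorted({g for c in clusters for g in c.genes if g not in gene_u})
        bad_s = sorted({s for c in clusters for s in c.samples if s not in sample_u})
        if bad_g or bad_s:
            raise ValueError(
                f"{path}: IDs outside the universe — genes {bad_g[:5]}, samples {bad_s[:5]}"
            )
    if matrix is not None:
        clusters = [
            Bicluster(c.genes, c.samples, set_snr(c.genes, c.samples, matrix))
            for c in clusters
        ]
    return clusters
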