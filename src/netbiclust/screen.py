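"""Rank-rank hypergeometric overlap (RRHO) screening of network edges.

For each gene pair connected in the interaction network, the samples are
ranked by each gene's expression and every prefix pair (top-i of one gene
vs top-j of the other, and bottom-i vs bottom-j for the concordant-low
tail) is scored with the upper-tail hypergeometric overlap probability.
The grid optimum defines the edge's shared sample set; the edge survives
if the optimal p-value passes the significance level and the set's SNR
exceeds a data-driven threshold (half the mean SNR of per-edge preliminary
hierarchical bipartitions).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

from .data_io import ExpressionMatrix, GeneNetwork
from .merge import SAMPLE_FRACTION_CAP, bipartition_samples
from .snr import gene_snr, set_snr

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "EdgeEvidence",
    "overlap_pvalue",
    "rrho_edge",
    "preliminary_snr_threshold",
    "screen_network_edges",
    "retained_network",
]

Direction = Literal["concordant-high", "concordant-low"]


@dataclass(frozen=True)
class EdgeEvidence:
    """A network edge with its RRHO-optimal supporting sample set."""

    gene_a: str
    gene_b: str
    samples: frozenset[str]
    p_min: float
    direction: Direction
    snr: float


@dataclass
class ScreenConfig:
    """Screening knobs.

    ``p_threshold`` is the raw significance level applied to each edge's
    minimal overlap p-value (no multiple-testing correction by default, as
    the downstream SNR filter does the heavy lifting); ``snr_threshold``
    is either a number or ``"auto"`` for the data-driven half-mean rule.
    """

    p_threshold: float = 0.01
    rank_step: int = 1
    snr_threshold: float | str = "auto"
    tails: Literal["both", "high"] = "both"
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if self.p_threshold not in (0.01, 0.05):
            logger.warning(
                "p_threshold %.4g outside the usual {0.01, 0.05}", self.p_threshold
            )
        if self.rank_step < 1:
            raise ValueError("rank_step must be >= 1")


def overlap_pvalue(n_total: int, size_a: int, size_b: int, overlap: int) -> float:
    """Upper-tail hypergeometric overlap probability P[X >= overlap].

    X counts the overlap of a fixed set of ``size_a`` items with a uniform
    random subset of ``size_b`` drawn from ``n_total``.
    """
    if not (0 <= size_a <= n_total and 0 <= size_b <= n_total):
        raise ValueError("set sizes must lie within the universe")
    if not (0 <= overlap <= min(size_a, size_b)):
        raise ValueError("overlap inconsistent with the set sizes")
    return float(hypergeom.sf(overlap - 1, n_total, size_a, size_b))


@lru_cache(maxsize=4)
def _sf_cube(n: int) -> np.ndarray:
    """Dense lookup ``cube[a, b, o] = P[X >= o]`` for a universe of size n.

    Built once per universe size from the log-pmf (gammaln) and a reversed
    cumulative sum over the overlap axis; infeasible (a, b, o) combinations
    hold probability zero mass and the tail saturates at 1.
    """
    a = np.arange(n + 1)[:, None, None].astype(float)
    b = np.arange(n + 1)[None, :, None].astype(float)
    o = np.arange(n + 1)[None, None, :].astype(float)
    with np.errstate(invalid="ignore"):
        logpmf = (
            gammaln(a + 1) - gammaln(o + 1) - gammaln(a - o + 1)
            + gammaln(n - a + 1) - gammaln(b - o + 1) - gammaln(n - a - b + o + 1)
            - (gammaln(n + 1) - gammaln(b + 1) - gammaln(n - b + 1))
        )
    bad = (o > a) | (o > b) | (b - o > n - a)
    pmf = np.exp(logpmf)
    pmf[bad] = 0.0
    sf = np.cumsum(pmf[:, :, ::-1], axis=2)[:, :, ::-1]
    return np.clip(sf, 0.0, 1.0)


def _rank_order(values: np.ndarray, descending: bool) -> np.ndarray:
    """Stable sample ordering; ties keep the original sample index order."""
    return np.argsort(-values if descending else values, kind="stable")


def _overlap_table(order_a: np.ndarray, order_b: np.ndarray) -> np.ndarray:
    """``O[i-1, j-1]`` = |top-i(order_a) ∩ top-j(order_b)| via 2-D prefix sums."""
    n = order_a.size
    pos_b = np.empty(n, dtype=np.intp)
    pos_b[order_b] = np.arange(n)
    perm = pos_b[order_a]
    mat = np.zeros((n, n), dtype=np.int32)
    mat[np.arange(n), perm] = 1
    return mat.cumsum(axis=0).cumsum(axis=1)


def _grid_optimum(
    p_grid: np.ndarray, idx: np.ndarray
) -> tuple[float, int, int]:
    """Minimal p over the grid, tie-broken by smallest i+j then smallest i."""
    p_min = float(p_grid.min())
    cells = np.argwhere(p_grid == p_min)
    sums = cells.sum(axis=1)
    cells = cells[sums == sums.min()]
    r, c = min(map(tuple, cells))
    return p_min, int(idx[r]), int(idx[c])


def rrho_edge(
    g1: str, g2: str, m: ExpressionMatrix, cfg: ScreenConfig | None = None
) -> EdgeEvidence:
    """RRHO optimum for one gene pair.

    Prefix thresholds run over i, j in {2, ..., n-2} (singleton prefixes are
    excluded as noise) with step ``cfg.rank_step``.  Both concordant tails
    are searched unless restricted; ties prefer smaller i+j, then the
    concordant-high tail.  The returned sample set is the intersection of
    the two optimal prefixes.
    """
    cfg = cfg or ScreenConfig()
    if m.n_samples < 4:
        raise ValueError("need at least 4 samples for RRHO screening")
    n = m.n_samples
    cube = _sf_cube(n)
    v1, v2 = m.gene_values(g1), m.gene_values(g2)
    idx = np.arange(2, n - 1, cfg.rank_step)  # 1-based prefix lengths 2..n-2

    best = None  # (p, i+j, tail_rank, i, j, direction, oa, ob)
    tails: list[Direction] = ["concordant-high"]
    if cfg.tails == "both":
        tails.append("concordant-low")
    for tail_rank, direction in enumerate(tails):
        descending = direction == "concordant-high"
        oa = _rank_order(v1, descending)
        ob = _rank_order(v2, descending)
        table = _overlap_table(oa, ob)
        sub_o = table[np.ix_(idx - 1, idx - 1)]
        p_grid = cube[idx[:, None], idx[None, :], sub_o]
        p_min, i, j = _grid_optimum(p_grid, idx)
        cand = (p_min, i + j, tail_rank, i, j, direction, oa, ob)
        if best is None or cand[:4] < best[:4]:
            best = cand
    p_min, _, _, i, j, direction, oa, ob = best
    samples = frozenset(
        m.sample_ids[s] for s in (set(oa[:i].tolist()) & set(ob[:j].tolist()))
    )
    if not samples:
        # an optimum with empty intersection cannot happen: overlap >= 1 is
        # required for the sf to dip below 1, but guard for degenerate grids
        samples = frozenset({m.sample_ids[int(oa[0])]})
    snr = 0.5 * (gene_snr(g1, samples, m) + gene_snr(g2, samples, m))
    return EdgeEvidence(g1, g2, samples, p_min, direction, snr)


def preliminary_snr_threshold(
    m: ExpressionMatrix, net: GeneNetwork, cap: float = SAMPLE_FRACTION_CAP
) -> float:
    """Half the mean SNR of per-edge preliminary hierarchical bipartitions.

    Each edge's samples are Ward-bipartitioned on the two genes' expression;
    the higher-SNR branch under the sample cap is the edge's preliminary
    set.  The threshold is half the mean of those sets' SNRs.
    """
    if net.n_edges == 0:
        raise ValueError("empty network")
    snrs = []
    limit = cap * m.n_samples
    for a, b in net.edges:
        try:
            parts = bipartition_samples([a, b], m)
        except ValueError:
            continue
        best = None
        for part in parts:
            if len(part) >= limit:
                continue
            s = set_snr([a, b], part, m)
            if best is None or s > best:
                best = s
        if best is not None:
            snrs.append(best)
    if not snrs:
        raise ValueError("no edge produced a valid preliminary bipartition")
    return 0.5 * float(np.mean(snrs))


def screen_network_edges(
    m: ExpressionMatrix, net: GeneNetwork, cfg: ScreenConfig | None = None
) -> tuple[list[EdgeEvidence], float]:
    """Screen every network edge; keep those passing both filters.

    Returns the retained evidence (p_min <= p_threshold and SNR strictly
    above the threshold) together with the SNR threshold actually applied.
    """
    cfg = cfg or ScreenConfig()
    if isinstance(cfg.snr_threshold, str):
        threshold = preliminary_snr_threshold(m, net)
        logger.info("auto SNR threshold: %.4f", threshold)
    else:
        threshold = float(cfg.snr_threshold)
    evidence = [rrho_edge(a, b, m, cfg) for a, b in net.edges]
    p_values = np.array([e.p_min for e in evidence])
    if cfg.bh_correct and p_values.size:
        order = np.argsort(p_values)
        ranked = p_values[order] * p_values.size / (np.arange(p_values.size) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.empty_like(p_values)
        adjusted[order] = np.clip(adj, 0, 1)
        p_values = adjusted
    kept = [
        e for e, p in zip(evidence, p_values)
        if p <= cfg.p_threshold and e.snr > threshold
    ]
    logger.info(
        "screening: retained %d / %d edges (p<=%.3g, snr>%.4f)",
        len(kept), len(evidence), cfg.p_threshold, threshold,
    )
    if not kept:
        raise ValueError(
            "no edge survived screening; consider relaxing p_threshold or "
            "snr_threshold"
        )
    return kept, threshold


def retained_network(evidence: Iterable[EdgeEvidence]) -> GeneNetwork:
    """The working network induced by retained edges (isolated genes gone)."""
    return GeneNetwork.from_edges((e.gene_a, e.gene_b) for e in evidence)


def write_evidence_tsv(evidence: Iterable[EdgeEvidence], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tp_min\tdirection\tsnr\tsamples\n")
        for e in evidence:
            fh.write(
                f"{e.gene_a}\t{e.gene_b}\t{e.p_min:.6g}\t{e.direction}\t"
                f"{e.snr:.6g}\t{';'.join(sorted(e.samples))}\n"
            )
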