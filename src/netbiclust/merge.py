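"""Iterative bicluster merging driven by Fisher's exact test.

Two biclusters are candidates for merging based on a two-sided Fisher exact
test of their sample-membership 2x2 table over the sample universe.  An
accepted merge re-derives the merged sample set by Ward hierarchical
bipartition of the samples on the union gene set, and must satisfy the
55%-of-samples cap and the SNR threshold.  Passes repeat until a full pass
accepts nothing.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln

from .data_io import Bicluster, ExpressionMatrix
from .snr import set_snr

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_overlap_test",
    "bipartition_samples",
    "try_merge",
    "iterative_merge",
    "MergeRejection",
    "MergeLogEntry",
    "SAMPLE_FRACTION_CAP",
]

#: a gene differentially expressed in more than half the samples is equally
#: well described as differentially expressed in the complement, so final
#: sample sets are capped strictly below this fraction of the universe
SAMPLE_FRACTION_CAP = 0.55

MergeDirection = Literal["not_different", "similar"]


@dataclass(frozen=True)
class MergeRejection:
    """Outcome of a merge attempt that failed, naming the failed criterion."""

    reason: str  # one of: fisher, no_split, cap, snr


@dataclass(frozen=True)
class MergeLogEntry:
    pass_no: int
    cluster_a: int
    cluster_b: int
    fisher_p: float
    accepted: bool
    reason: str  # "merged" or the rejection reason


from functools import lru_cache


@lru_cache(maxsize=8)
def _gammaln_table(n: int) -> np.ndarray:
    return gammaln(np.arange(n + 2).astype(float))


def _two_sided_fisher_p(n: int, na: int, nb: int, overlap: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table with margins (na, nb) in n.

    Sums the probabilities of all hypergeometric tables no more likely than
    the observed one (the standard two-sided convention, with the usual
    1 + 1e-7 relative tolerance on the pmf comparison).
    """
    lo = max(0, na + nb - n)
    hi = min(na, nb)
    x = np.arange(lo, hi + 1)
    gl = _gammaln_table(n)
    logpmf = (
        gl[na + 1] - gl[x + 1] - gl[na - x + 1]
        + gl[n - na + 1] - gl[nb - x + 1] - gl[n - na - nb + x + 1]
        - (gl[n + 1] - gl[nb + 1] - gl[n - nb + 1])
    )
    pmf = np.exp(logpmf)
    p = float(pmf[pmf <= pmf[overlap - lo] * (1 + 1e-7)].sum())
    return min(p, 1.0)


def fisher_overlap_test(a: Bicluster, b: Bicluster, all_samples: Sequence[str]) -> float:
    """Two-sided Fisher exact p for association of two sample memberships.

    The 2x2 table counts the sample universe by (in a) x (in b).  Degenerate
    tables (an empty or universe-covering set) carry no information and
    return p = 1 with a warning.
    """
    universe = set(all_samples)
    sa, sb = set(a.samples) & universe, set(b.samples) & universe
    n = len(universe)
    if not sa or not sb or len(sa) == n or len(sb) == n:
        warnings.warn("degenerate sample set in Fisher overlap test; p = 1")
        return 1.0
    return _two_sided_fisher_p(n, len(sa), len(sb), len(sa & sb))


def bipartition_samples(
    genes: Sequence[str], m: ExpressionMatrix
) -> tuple[frozenset[str], frozenset[str]]:
    """Split the samples into two groups by Ward clustering on the gene rows.

    Sample columns restricted to ``genes`` are clustered (Euclidean, Ward)
    and the dendrogram is cut at two clusters.  Deterministic for a given
    matrix; permutation of the sample columns permutes nothing as sets.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    if m.n_samples < 4:
        raise ValueError("need at least 4 samples to bipartition")
    rows = np.vstack([m.gene_values(g) for g in genes])
    x = rows.T  # samples as observations
    if np.allclose(x, x[0], atol=0, rtol=0):
        raise ValueError("all sample profiles identical; no bipartition exists")
    labels = fcluster(linkage(x, method="ward"), t=2, criterion="maxclust")
    part1 = frozenset(s for s, lab in zip(m.sample_ids, labels) if lab == 1)
    part2 = frozenset(s for s, lab in zip(m.sample_ids, labels) if lab == 2)
    if not part1 or not part2:
        raise ValueError("degenerate bipartition")
    return part1, part2


def _pick_branch(
    genes: Sequence[str],
    parts: tuple[frozenset[str], frozenset[str]],
    m: ExpressionMatrix,
    cap: float = SAMPLE_FRACTION_CAP,
    reference: frozenset[str] | None = None,
) -> tuple[frozenset[str], float] | None:
    """Pick the candidate branch of a bipartition.

    The two branches of a bipartition are complements, and the
    absolute-value SNR is symmetric between a set and its complement, so
    both branches carry one SNR value and "higher SNR" cannot discriminate.
    Selection therefore falls to the constraints: only under-cap branches
    qualify; among those, the branch covering more of ``reference`` (the
    merging clusters' own sample sets) wins, then the smaller branch
    (differential sets are minority sets), then lexicographic sample IDs.
    """
    limit = cap * m.n_samples
    qualifying = [p for p in parts if len(p) < limit]
    if not qualifying:
        return None
    ref = reference or frozenset()
    pick = min(qualifying, key=lambda p: (-len(p & ref), len(p), sorted(p)))
    return pick, set_snr(genes, pick, m)


def try_merge(
    a: Bicluster,
    b: Bicluster,
    m: ExpressionMatrix,
    snr_threshold: float,
    fisher_alpha: float = 0.05,
    direction: MergeDirection = "similar",
    fisher_p: float | None = None,
) -> Bicluster | MergeRejection:
    """Attempt to merge two biclusters; rejection is a value, not an error.

    ``direction`` selects the Fisher criterion: ``"not_different"`` merges
    when the two sample sets are not significantly different (p > alpha);
    ``"similar"`` merges only when they are significantly positively
    associated (p <= alpha with more overlap than expected by chance).
    """
    if fisher_p is None:
        fisher_p = fisher_overlap_test(a, b, m.sample_ids)
    if direction == "not_different":
        if fisher_p <= fisher_alpha:
            return MergeRejection("fisher")
    else:
        both = len(a.samples & b.samples)
        expected = len(a.samples) * len(b.samples) / m.n_samples
        if fisher_p > fisher_alpha or both <= expected:
            return MergeRejection("fisher")
    union_genes = sorted(a.genes | b.genes)
    try:
        parts = bipartition_samples(union_genes, m)
    except ValueError:
        return MergeRejection("no_split")
    picked = _pick_branch(union_genes, parts, m, reference=a.samples | b.samples)
    if picked is None:
        return MergeRejection("cap")
    samples, snr = picked
    if snr <= snr_threshold:
        return MergeRejection("snr")
    return Bicluster(frozenset(union_genes), samples, snr)


def iterative_merge(
    clusters: Sequence[Bicluster],
    m: ExpressionMatrix,
    snr_threshold: float,
    fisher_alpha: float = 0.05,
    direction: MergeDirection = "similar",
) -> tuple[list[Bicluster], list[MergeLogEntry]]:
    """Merge cyclically until a full pass accepts nothing.

    Within each pass, pairs are attempted in ascending order of Fisher p
    (ties broken by cluster index) and a cluster takes part in at most one
    accepted merge per pass.  Every accepted merge strictly decreases the
    cluster count, so the procedure terminates.  Output is sorted by
    descending average SNR.
    """
    current = list(clusters)
    if not current:
        raise ValueError("no clusters to merge")
    log: list[MergeLogEntry] = []
    p_cache: dict[tuple, float] = {}
    # a rejected pair re-attempted in a later pass is unchanged content-wise,
    # so its outcome is cached and only pairs touching a new cluster re-run
    attempt_cache: dict[tuple, Bicluster | MergeRejection] = {}

    def _pair_key(a: Bicluster, b: Bicluster) -> tuple:
        ka, kb = (a.genes, a.samples), (b.genes, b.samples)
        return (ka, kb) if (sorted(a.genes), sorted(a.samples)) <= (
            sorted(b.genes), sorted(b.samples)
        ) else (kb, ka)

    def cached_p(a: Bicluster, b: Bicluster) -> float:
        # the test depends only on the two sample sets
        key = tuple(sorted((a.samples, b.samples), key=sorted))
        if key not in p_cache:
            p_cache[key] = fisher_overlap_test(a, b, m.sample_ids)
        return p_cache[key]

    pass_no = 0
    while True:
        pass_no += 1
        pairs = [
            (cached_p(current[i], current[j]), i, j)
            for i in range(len(current))
            for j in range(i + 1, len(current))
        ]
        pairs.sort()
        consumed: set[int] = set()
        accepted: list[Bicluster] = []
        any_merge = False
        for p, i, j in pairs:
            if i in consumed or j in consumed:
                continue
            key = _pair_key(current[i], current[j])
            if key in attempt_cache:
                result = attempt_cache[key]
            else:
                result = try_merge(
                    current[i], current[j], m, snr_threshold, fisher_alpha,
                    direction=direction, fisher_p=p,
                )
                attempt_cache[key] = result
                log.append(
                    MergeLogEntry(
                        pass_no, i, j, p,
                        isinstance(result, Bicluster),
                        "merged" if isinstance(result, Bicluster) else result.reason,
                    )
                )
            if isinstance(result, Bicluster):
                consumed.update((i, j))
                accepted.append(result)
                any_merge = True
        if not any_merge:
            break
        current = [c for k, c in enumerate(current) if k not in consumed] + accepted
    # final outputs must honour the sample cap and sit above the SNR floor
    limit = SAMPLE_FRACTION_CAP * m.n_samples
    n_before = len(current)
    current = [
        c for c in current if len(c.samples) < limit and c.avg_snr > snr_threshold
    ]
    if len(current) < n_before:
        logger.info(
            "dropped %d clusters violating the sample cap or SNR floor",
            n_before - len(current),
        )
    current.sort(key=lambda c: (-c.avg_snr, sorted(c.genes)))
    return current, log
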