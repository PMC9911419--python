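"""Collapsed Gibbs sampling of a Bernoulli mixture over edge membership rows.

Each retained edge j contributes a binary row x[j, i] over samples i (1 iff
sample i is in the edge's RRHO set).  Rows are modelled as a K-component
mixture of independent Bernoullis with symmetric Beta(alpha/2, alpha/2)
priors on the rates and a symmetric Dirichlet(beta/K) prior on the mixture
weights; both continuous parameter blocks are integrated out, leaving a
label-only Gibbs sampler whose full conditional for edge j is

  P(s_j = k | X, s_-j) ∝ (n_k + beta/K) / (n - 1 + beta)
      * prod_{i: x_ji=1} (alpha/2 + c1_ki) / (alpha + n_k)
      * prod_{i: x_ji=0} (alpha/2 + c0_ki) / (alpha + n_k)

with n_k, c1_ki, c0_ki counted over the other edges currently in k.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import Bicluster, ExpressionMatrix
from .screen import EdgeEvidence
from .snr import set_snr

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeMembershipMatrix",
    "GibbsConfig",
    "GibbsResult",
    "build_membership_matrix",
    "conditional_weights",
    "run_gibbs",
    "extract_modules",
]

try:  # pragma: no cover - exercised implicitly by every sampler test
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class EdgeMembershipMatrix:
    """Binary edge x sample membership indicators."""

    edge_ids: list[tuple[str, str]]
    sample_ids: list[str]
    x: np.ndarray  # (n_edges, n_samples) uint8

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.uint8)
        if self.x.shape != (len(self.edge_ids), len(self.sample_ids)):
            raise ValueError("membership matrix shape mismatch")
        if not set(np.unique(self.x)) <= {0, 1}:
            raise ValueError("membership values must be binary")
        if (self.x.sum(axis=1) == 0).any():
            raise ValueError("every edge must have a non-empty sample set")

    @property
    def n_edges(self) -> int:
        return len(self.edge_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class GibbsConfig:
    """Sampler hyperparameters.

    ``alpha`` is the total Beta pseudo-count per Bernoulli rate (split as
    alpha/2 + alpha/2); ``beta_over_k`` the per-component Dirichlet
    pseudo-count, so the total concentration is beta = beta_over_k * K.
    Defaults alpha = 0.5 and beta/K = 1.0.
    """

    K: int
    alpha: float = 0.5
    beta_over_k: float = 1.0
    n_sweeps: int = 500
    n_burnin: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0 or self.beta_over_k <= 0:
            raise ValueError("alpha and beta/K must be positive")
        if not (0 <= self.n_burnin < self.n_sweeps):
            raise ValueError("need 0 <= n_burnin < n_sweeps")

    @property
    def beta(self) -> float:
        return self.beta_over_k * self.K


@dataclass
class GibbsResult:
    """Point estimate plus the retained post-burn-in label trajectories."""

    assignments: np.ndarray  # (n_edges,) modal labels in 0..K-1
    states: np.ndarray  # (n_kept_sweeps, n_edges) labels after each sweep
    visits: np.ndarray  # (n_edges, K) post-burn-in label counts


def build_membership_matrix(
    evidence: Sequence[EdgeEvidence], sample_ids: Sequence[str]
) -> EdgeMembershipMatrix:
    """Indicator rows from retained edge evidence, in evidence order."""
    if not evidence:
        raise ValueError("no edge evidence")
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    x = np.zeros((len(evidence), len(sample_ids)), dtype=np.uint8)
    for j, e in enumerate(evidence):
        unknown = set(e.samples) - sample_index.keys()
        if unknown:
            raise ValueError(f"edge {e.gene_a}-{e.gene_b} references unknown samples: {sorted(unknown)[:5]}")
        x[j, [sample_index[s] for s in e.samples]] = 1
    return EdgeMembershipMatrix([(e.gene_a, e.gene_b) for e in evidence], list(sample_ids), x)


def conditional_weights(
    j: int, x: EdgeMembershipMatrix, s: np.ndarray, cfg: GibbsConfig
) -> np.ndarray:
    """Unnormalized full-conditional weights for edge j (log-space internally).

    ``s`` holds the current labels of all edges; edge j's own label is
    ignored (it is excluded from every count).
    """
    K, alpha, beta = cfg.K, cfg.alpha, cfg.beta
    mask = np.ones(x.n_edges, dtype=bool)
    mask[j] = False
    xs = x.x[mask].astype(np.int64)
    labels = np.asarray(s)[mask]
    n = x.n_edges
    nk = np.bincount(labels, minlength=K).astype(float)
    c1 = np.zeros((K, x.n_samples))
    np.add.at(c1, labels, xs)
    c0 = nk[:, None] - c1
    row = x.x[j].astype(bool)
    logw = (
        np.log(nk + beta / K)
        - np.log(n - 1 + beta)
        + np.log(alpha / 2 + c1[:, row]).sum(axis=1)
        + np.log(alpha / 2 + c0[:, ~row]).sum(axis=1)
        - x.n_samples * np.log(alpha + nk)
    )
    if not np.all(np.isfinite(logw)):
        raise RuntimeError("non-finite conditional weight")
    return np.exp(logw)


def _sweep_python(x, ones_idx, ones_ptr, s, K, alpha, beta, n_sweeps, n_burnin, u, states):
    """Reference sweep loop; mirrors the compiled kernel exactly.

    Per occupied label k two quantities are cached and maintained
    incrementally: F[k], the log-likelihood contribution of an all-zero row
    (-n log(alpha+n_k) + sum_i log(alpha/2 + c0_ki)), and L[k, i], the
    per-sample log-odds correction log(alpha/2 + c1_ki) - log(alpha/2 +
    c0_ki), so an edge's weight for label k costs O(|ones|).  Empty labels
    all share one closed-form weight, so only occupied labels are scanned.
    """
    E, n = x.shape
    betaK = beta / K
    logtab = np.log(alpha / 2 + np.arange(E + 1, dtype=np.float64))
    nk = np.zeros(K, dtype=np.int64)
    c1 = np.zeros((K, n), dtype=np.int64)
    for j in range(E):
        nk[s[j]] += 1
        for q in range(ones_ptr[j], ones_ptr[j + 1]):
            c1[s[j], ones_idx[q]] += 1
    F = np.zeros(K, dtype=np.float64)
    L = np.zeros((K, n), dtype=np.float64)
    f_empty = -n * np.log(alpha) + n * logtab[0]
    for k in range(K):
        if nk[k] == 0:
            F[k] = f_empty
        else:
            acc = -n * np.log(alpha + nk[k])
            for i in range(n):
                c0 = nk[k] - c1[k, i]
                acc += logtab[c0]
                L[k, i] = logtab[c1[k, i]] - logtab[c0]
            F[k] = acc
    # occupied-label bookkeeping: a membership flag, a dense list, and a
    # stack of free labels (LIFO); which empty label represents "new" is
    # immaterial by symmetry of the prior
    occ_list = np.empty(K, dtype=np.int64)
    occ_pos = np.full(K, -1, dtype=np.int64)
    n_occ = 0
    free_stack = np.empty(K, dtype=np.int64)
    n_free = 0
    for k in range(K - 1, -1, -1):
        if nk[k] > 0:
            occ_list[n_occ] = k
            occ_pos[k] = n_occ
            n_occ += 1
        else:
            free_stack[n_free] = k
            n_free += 1
    w = np.empty(K, dtype=np.float64)
    log_betaK = np.log(betaK)
    for t in range(n_sweeps):
        for j in range(E):
            k_old = s[j]
            nk[k_old] -= 1
            for q in range(ones_ptr[j], ones_ptr[j + 1]):
                c1[k_old, ones_idx[q]] -= 1
            if nk[k_old] == 0:
                F[k_old] = f_empty
                for i in range(n):
                    L[k_old, i] = 0.0
                pos = occ_pos[k_old]
                n_occ -= 1
                last = occ_list[n_occ]
                occ_list[pos] = last
                occ_pos[last] = pos
                occ_pos[k_old] = -1
                free_stack[n_free] = k_old
                n_free += 1
            else:
                acc = -n * np.log(alpha + nk[k_old])
                for i in range(n):
                    c0 = nk[k_old] - c1[k_old, i]
                    acc += logtab[c0]
                    L[k_old, i] = logtab[c1[k_old, i]] - logtab[c0]
                F[k_old] = acc
            # weights: occupied labels individually, empties share one value
            mx = log_betaK + f_empty
            for p in range(n_occ):
                k = occ_list[p]
                acc = np.log(nk[k] + betaK) + F[k]
                for q in range(ones_ptr[j], ones_ptr[j + 1]):
                    acc += L[k, ones_idx[q]]
                w[p] = acc
                if acc > mx:
                    mx = acc
            total = 0.0
            for p in range(n_occ):
                w[p] = np.exp(w[p] - mx)
                total += w[p]
            w_empty = np.exp(log_betaK + f_empty - mx)
            total += n_free * w_empty
            target = u[t, j] * total
            run = 0.0
            k_new = -1
            for p in range(n_occ):
                run += w[p]
                if run >= target:
                    k_new = occ_list[p]
                    break
            if k_new < 0 and n_free == 0:
                # rounding pushed the target past the cumulative sum
                k_new = occ_list[n_occ - 1]
            elif k_new < 0:  # landed in the pooled empty mass
                k_new = free_stack[n_free - 1]
                n_free -= 1
                occ_list[n_occ] = k_new
                occ_pos[k_new] = n_occ
                n_occ += 1
            s[j] = k_new
            nk[k_new] += 1
            for q in range(ones_ptr[j], ones_ptr[j + 1]):
                c1[k_new, ones_idx[q]] += 1
            acc = -n * np.log(alpha + nk[k_new])
            for i in range(n):
                c0 = nk[k_new] - c1[k_new, i]
                acc += logtab[c0]
                L[k_new, i] = logtab[c1[k_new, i]] - logtab[c0]
            F[k_new] = acc
        if t >= n_burnin:
            states[t - n_burnin] = s
    return s


if _HAVE_NUMBA:
    _sweep_kernel = numba.njit(cache=True)(_sweep_python)
else:  # pragma: no cover
    _sweep_kernel = _sweep_python


def run_gibbs(
    x: EdgeMembershipMatrix, cfg: GibbsConfig, init: np.ndarray | None = None
) -> GibbsResult:
    """Run the collapsed sampler; deterministic for a fixed seed.

    Edges are resampled in fixed (input) order within each sweep.  ``init``
    optionally supplies starting labels (e.g. retained-network component
    indices, the natural companion of the component-count rule for K);
    without it labels are spread round-robin.  The point estimate is each
    edge's modal label over post-burn-in sweeps, which is considerably more
    stable across seeds than the final sweep.
    """
    E, n = x.x.shape
    rng = np.random.default_rng(cfg.seed)
    u = rng.random((cfg.n_sweeps, E))
    ones_lists = [np.flatnonzero(x.x[j]).astype(np.int64) for j in range(E)]
    ones_ptr = np.zeros(E + 1, dtype=np.int64)
    ones_ptr[1:] = np.cumsum([len(o) for o in ones_lists])
    ones_idx = np.concatenate(ones_lists) if ones_lists else np.zeros(0, dtype=np.int64)
    if init is not None:
        s = np.asarray(init, dtype=np.int64).copy() % cfg.K
        if s.shape != (E,):
            raise ValueError("init labels must have one entry per edge")
    else:
        s = np.arange(E, dtype=np.int64) % cfg.K  # spread initial labels
    n_kept = cfg.n_sweeps - cfg.n_burnin
    states = np.zeros((n_kept, E), dtype=np.int64)
    _sweep_kernel(
        x.x, ones_idx, ones_ptr, s, cfg.K, float(cfg.alpha), float(cfg.beta),
        cfg.n_sweeps, cfg.n_burnin, u, states,
    )
    visits = np.zeros((E, cfg.K), dtype=np.int64)
    for j in range(E):
        visits[j] = np.bincount(states[:, j], minlength=cfg.K)
    assignments = visits.argmax(axis=1)
    return GibbsResult(assignments, states, visits)


def extract_modules(
    assignments: np.ndarray,
    x: EdgeMembershipMatrix,
    m: ExpressionMatrix,
    alpha: float = 0.5,
) -> list[Bicluster]:
    """Turn edge modules into biclusters.

    Per non-empty component: genes are the union of edge endpoints; samples
    are those whose posterior Bernoulli mean (c1 + alpha/2) / (n_k + alpha)
    exceeds 1/2; the average SNR is recomputed from the expression matrix.
    Components whose sample set comes out empty are dropped with a warning.
    """
    assignments = np.asarray(assignments)
    out: list[Bicluster] = []
    for k in np.unique(assignments):
        rows = np.flatnonzero(assignments == k)
        n_k = rows.size
        c1 = x.x[rows].sum(axis=0)
        rate = (c1 + alpha / 2) / (n_k + alpha)
        sample_idx = np.flatnonzero(rate > 0.5)
        if sample_idx.size == 0:
            warnings.warn(f"component {k}: no sample passes the 0.5 posterior rate; dropped")
            continue
        if sample_idx.size == x.n_samples:
            # a set covering every sample has no complement to differ from
            warnings.warn(f"component {k}: sample set covers the whole universe; dropped")
            continue
        genes = frozenset(g for j in rows for g in x.edge_ids[j])
        samples = frozenset(x.sample_ids[i] for i in sample_idx)
        out.append(Bicluster(genes, samples, set_snr(genes, samples, m)))
    return out
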