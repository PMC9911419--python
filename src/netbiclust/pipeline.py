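"""End-to-end pipeline: impute -> normalize -> prune -> screen -> sample -> merge.

One global seed fans out to per-stage generators through a stable
stage-name hash, so any stage can be re-run in isolation with the same
stream it saw inside the full pipeline.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass
from typing import Literal

import networkx as nx
import numpy as np

from . import data_io, evaluate, merge, sampler, screen, simulate
from .data_io import Bicluster, ExpressionMatrix, GeneNetwork
from .snr import set_snr

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "benchmark_cell", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the global seed and stage name."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the study's selected hyperparameters."""

    p_threshold: float = 0.01
    rank_step: int = 1
    snr_threshold: float | str = "auto"
    tails: Literal["both", "high"] = "both"
    alpha: float = 0.5
    beta_over_k: float = 1.0
    K: int | None = None  # None -> number of retained-edge components
    n_sweeps: int = 300
    n_burnin: int = 150
    fisher_alpha: float = 0.01
    merge_direction: merge.MergeDirection = "similar"
    knn_k: int = 10
    seed: int = 0

    def screen_config(self) -> screen.ScreenConfig:
        return screen.ScreenConfig(
            p_threshold=self.p_threshold,
            rank_step=self.rank_step,
            snr_threshold=self.snr_threshold,
            tails=self.tails,
        )


@dataclass
class PipelineResult:
    biclusters: list[Bicluster]
    evidence: list[screen.EdgeEvidence]
    snr_threshold: float
    assignments: np.ndarray
    membership: sampler.EdgeMembershipMatrix
    pre_merge: list[Bicluster]
    merge_log: list[merge.MergeLogEntry]
    n_components: int


def run_pipeline(
    m: ExpressionMatrix, net: GeneNetwork, config: RunConfig | None = None
) -> PipelineResult:
    """Run the full method on an expression matrix and gene network."""
    config = config or RunConfig()
    if m.n_missing:
        m = data_io.knn_impute(m, k=config.knn_k)
    m = data_io.normalize_per_gene(m)
    net, m = data_io.prune_isolated_genes(net, m)

    evidence, threshold = screen.screen_network_edges(m, net, config.screen_config())
    retained = screen.retained_network(evidence)
    n_components = nx.number_connected_components(retained.graph)
    # after screening, each retained gene pair with its sample set is itself
    # a (two-gene) cluster, so the mixture gets one component per retained
    # edge and the sampler coalesces labels from a singleton start
    K = config.K if config.K is not None else len(evidence)
    logger.info("retained %d edges in %d components; K=%d", len(evidence), n_components, K)

    x = sampler.build_membership_matrix(evidence, m.sample_ids)
    gibbs_cfg = sampler.GibbsConfig(
        K=K,
        alpha=config.alpha,
        beta_over_k=config.beta_over_k,
        n_sweeps=config.n_sweeps,
        n_burnin=config.n_burnin,
        seed=stage_seed(config.seed, "gibbs"),
    )
    init = np.arange(x.n_edges, dtype=np.int64)
    result = sampler.run_gibbs(x, gibbs_cfg, init=init)
    pre_merge = sampler.extract_modules(result.assignments, x, m, alpha=config.alpha)
    logger.info("extracted %d edge modules", len(pre_merge))

    if pre_merge:
        final, merge_log = merge.iterative_merge(
            pre_merge, m, threshold, config.fisher_alpha, direction=config.merge_direction
        )
    else:
        final, merge_log = [], []
    logger.info("final bicluster count: %d", len(final))
    return PipelineResult(
        biclusters=final,
        evidence=evidence,
        snr_threshold=threshold,
        assignments=result.assignments,
        membership=x,
        pre_merge=pre_merge,
        merge_log=merge_log,
        n_components=n_components,
    )


def benchmark_cell(
    samples_per_module: int,
    genes_per_module: int,
    replicates: int = 5,
    seed: int = 0,
    config: RunConfig | None = None,
    spec: simulate.SimulationSpec | None = None,
) -> dict:
    """Simulate -> run -> evaluate for one fixed module size, over replicates.

    Returns the per-replicate recovery Jaccards and their mean/SD, using
    the benchmark's standard 2000 x 200 matrix with 20 planted modules of
    the requested (samples, genes) size.
    """
    base_spec = spec or simulate.SimulationSpec()
    scores: list[float] = []
    reports: list[evaluate.EvaluationReport] = []
    constraint_violations = 0
    for r in range(replicates):
        rep_seed = stage_seed(seed, f"replicate-{r}")
        rep_spec = simulate.SimulationSpec(
            **{
                **asdict(base_spec),
                "fixed_module_size": (samples_per_module, genes_per_module),
                "seed": rep_seed,
            }
        )
        matrix, modules = simulate.generate_dataset(rep_spec)
        network = simulate.generate_network(modules, rep_spec)
        cfg = config or RunConfig()
        cfg = RunConfig(**{**asdict(cfg), "seed": rep_seed})
        try:
            result = run_pipeline(matrix, network, cfg)
            found = result.biclusters
        except ValueError as exc:  # e.g. no edge survived screening
            logger.warning("replicate %d failed: %s", r, exc)
            found = []
            result = None
        if result is not None:
            # every emitted bicluster must honour the sample cap and its
            # stored SNR must be reproducible from the raw matrix (gene-wise
            # z-scoring leaves the SNR unchanged, so the raw values suffice)
            for c in found:
                if len(c.samples) >= merge.SAMPLE_FRACTION_CAP * matrix.n_samples:
                    constraint_violations += 1
                recomputed = set_snr(c.genes, c.samples, matrix)
                if abs(recomputed - c.avg_snr) > 1e-6 or recomputed <= result.snr_threshold:
                    constraint_violations += 1
        report = evaluate.recovery_score(found, modules)
        scores.append(report.recovery)
        reports.append(report)
    return {
        "samples_per_module": samples_per_module,
        "genes_per_module": genes_per_module,
        "replicates": replicates,
        "scores": scores,
        "mean": float(np.mean(scores)),
        "sd": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
        "constraint_violations": constraint_violations,
        "reports": reports,
    }
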