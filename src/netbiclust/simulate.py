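"""Synthetic benchmark: planted mean-shifted modules plus a matching network.

The generator emulates the benchmark protocol the method is evaluated on:
a 2000-gene x 200-sample background of N(0, 1) noise into which 20 modules
are planted, each a uniformly drawn gene subset x sample subset whose cells
are overwritten with N(2, 1) draws.  Module gene counts come from the pool
(100, 50, 20, 10, 5) and sample counts from (100, 50, 20, 10); overlapping
modules are allowed (later modules overwrite shared cells).  The companion
gene network gives each planted module a connected induced subgraph (a
uniform spanning tree plus extra in-module edges) embedded in sparse
background edges.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import yaml

from .data_io import (
    ExpressionMatrix,
    GeneNetwork,
    write_edge_list,
    write_expression_table,
)

__all__ = [
    "SimulationSpec",
    "PlantedModule",
    "generate_dataset",
    "generate_network",
    "write_fixture",
    "load_truth",
]


@dataclass(frozen=True)
class PlantedModule:
    """Ground-truth bicluster injected by the generator."""

    genes: frozenset[str]
    samples: frozenset[str]


@dataclass
class SimulationSpec:
    """Benchmark conditions; defaults are the study's stated protocol."""

    n_genes: int = 2000
    n_samples: int = 200
    n_modules: int = 20
    gene_size_pool: tuple[int, ...] = (100, 50, 20, 10, 5)
    sample_size_pool: tuple[int, ...] = (100, 50, 20, 10)
    in_mean: float = 2.0
    in_sd: float = 1.0
    bg_mean: float = 0.0
    bg_sd: float = 1.0
    allow_overlap: bool = True
    seed: int = 0
    #: (n_samples_per_module, n_genes_per_module) override for fixed-size runs
    fixed_module_size: tuple[int, int] | None = None
    #: mean within-module degree of the companion network
    module_degree: float = 3.0
    #: mean background degree of the companion network; the benchmark's
    #: network is derived from the planted modules, so the default adds none
    background_degree: float = 0.0

    def __post_init__(self) -> None:
        if not self.gene_size_pool or not self.sample_size_pool:
            raise ValueError("size pools must be non-empty")
        if self.fixed_module_size is None:
            if max(self.gene_size_pool) > self.n_genes:
                raise ValueError("a pooled module gene count exceeds n_genes")
            if max(self.sample_size_pool) > self.n_samples:
                raise ValueError("a pooled module sample count exceeds n_samples")
        else:
            s, g = self.fixed_module_size
            if g > self.n_genes or s > self.n_samples:
                raise ValueError("fixed module size exceeds matrix dimensions")


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(spec: SimulationSpec) -> tuple[ExpressionMatrix, list[PlantedModule]]:
    """Expression matrix with planted modules; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    genes = _ids("g", spec.n_genes)
    samples = _ids("s", spec.n_samples)
    values = rng.normal(spec.bg_mean, spec.bg_sd, size=(spec.n_genes, spec.n_samples))
    modules: list[PlantedModule] = []
    for _ in range(spec.n_modules):
        if spec.fixed_module_size is not None:
            n_s, n_g = spec.fixed_module_size
        else:
            n_g = int(rng.choice(spec.gene_size_pool))
            n_s = int(rng.choice(spec.sample_size_pool))
        g_idx = rng.choice(spec.n_genes, size=n_g, replace=False)
        s_idx = rng.choice(spec.n_samples, size=n_s, replace=False)
        if not spec.allow_overlap:
            g_idx = np.array(
                [g for g in g_idx if not any(genes[g] in mod.genes for mod in modules)]
            )
            if g_idx.size == 0:
                raise ValueError("cannot place a non-overlapping module")
        values[np.ix_(g_idx, s_idx)] = rng.normal(spec.in_mean, spec.in_sd, size=(g_idx.size, n_s))
        modules.append(
            PlantedModule(
                frozenset(genes[g] for g in g_idx),
                frozenset(samples[s] for s in s_idx),
            )
        )
    return ExpressionMatrix(genes, samples, values), modules


def _prufer_tree(nodes: Sequence[str], rng: np.random.Generator) -> list[tuple[str, str]]:
    """Uniform random labelled tree on the given nodes (Prüfer sequence)."""
    n = len(nodes)
    if n == 1:
        return []
    if n == 2:
        return [(nodes[0], nodes[1])]
    seq = rng.integers(0, n, size=n - 2)
    tree = nx.from_prufer_sequence(list(int(v) for v in seq))
    return [(nodes[a], nodes[b]) for a, b in tree.edges]


def generate_network(modules: Sequence[PlantedModule], spec: SimulationSpec) -> GeneNetwork:
    """Companion gene network with connected per-module subgraphs.

    Each module's genes get a uniform spanning tree plus extra uniformly
    chosen in-module edges up to a mean within-module degree; background
    edges between uniformly chosen gene pairs bring the background degree up
    to its mean.  The result is a simple graph with no isolated module gene.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    g = nx.Graph()
    genes = _ids("g", spec.n_genes)
    for mod in modules:
        nodes = sorted(mod.genes)
        g.add_edges_from(_prufer_tree(nodes, rng))
        n = len(nodes)
        target = int(np.ceil(n * spec.module_degree / 2))
        guard = 0
        while g.subgraph(nodes).number_of_edges() < target and guard < 50 * target:
            a, b = rng.choice(n, size=2, replace=False)
            g.add_edge(nodes[a], nodes[b])
            guard += 1
    n_background = int(round(spec.n_genes * spec.background_degree / 2))
    added = 0
    guard = 0
    while added < n_background and guard < 50 * n_background:
        a, b = rng.choice(spec.n_genes, size=2, replace=False)
        u, v = genes[a], genes[b]
        guard += 1
        if g.has_edge(u, v):
            continue
        g.add_edge(u, v)
        added += 1
    return GeneNetwork(g)


def write_fixture(
    out_dir: str | Path,
    dataset: ExpressionMatrix,
    modules: Sequence[PlantedModule],
    network: GeneNetwork,
    spec: SimulationSpec | None = None,
) -> dict[str, Path]:
    """Write expression.tsv, network.tsv, truth.json and spec.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "network": out / "network.tsv",
        "truth": out / "truth.json",
        "spec": out / "spec.yaml",
    }
    write_expression_table(dataset, paths["expression"])
    write_edge_list(network, paths["network"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            [
                {"module": i, "genes": sorted(mo.genes), "samples": sorted(mo.samples)}
                for i, mo in enumerate(modules, start=1)
            ],
            fh,
            indent=1,
        )
    if spec is not None:
        with open(paths["spec"], "w") as fh:
            yaml.safe_dump(asdict(spec), fh)
    return paths


def load_truth(path: str | Path) -> list[PlantedModule]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        PlantedModule(frozenset(e["genes"]), frozenset(e["samples"])) for e in payload
    ]
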