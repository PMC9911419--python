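import numpy as np
import pytest

from netbiclust.data_io import ExpressionMatrix, GeneNetwork
from netbiclust.simulate import SimulationSpec, generate_dataset, generate_network


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples with an obvious two-block structure in g1/g2."""
    rng = np.random.default_rng(42)
    values = rng.normal(0, 1, size=(4, 6))
    values[0, :3] += 5.0
    values[1, :3] += 5.0
    return ExpressionMatrix(
        ["g1", "g2", "g3", "g4"],
        ["s1", "s2", "s3", "s4", "s5", "s6"],
        values,
    )


@pytest.fixture(scope="session")
def small_planted():
    """Down-scaled planted-module dataset: 120 genes x 40 samples, 4 modules.

    Strong (+5) effect so that every stage behaves deterministically enough
    for structural assertions without benchmark-scale compute.
    """
    spec = SimulationSpec(
        n_genes=120,
        n_samples=40,
        n_modules=4,
        in_mean=5.0,
        fixed_module_size=(12, 15),
        seed=7,
    )
    matrix, modules = generate_dataset(spec)
    network = generate_network(modules, spec)
    return spec, matrix, modules, network
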