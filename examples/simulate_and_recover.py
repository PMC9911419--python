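"""Plant differential co-expression modules, recover them, and score recovery.

Builds a down-scaled benchmark dataset (400 genes x 80 samples, 6 planted
modules of 20 samples x 20 genes with in-module values shifted by +2 noise
SDs), runs the full screening -> Gibbs -> merging pipeline, and reports the
mean best-match cell-level Jaccard between recovered and planted biclusters.
"""
import numpy as np

from netbiclust import (
    RunConfig,
    SimulationSpec,
    generate_dataset,
    generate_network,
    recovery_score,
    run_pipeline,
)

spec = SimulationSpec(
    n_genes=400,
    n_samples=80,
    n_modules=6,
    fixed_module_size=(20, 20),  # (samples, genes) per module
    in_mean=2.0,
    seed=42,
)
matrix, truth = generate_dataset(spec)
network = generate_network(truth, spec)
print(f"dataset: {matrix.n_genes} genes x {matrix.n_samples} samples, "
      f"{len(truth)} planted modules, {network.n_edges} network edges")

result = run_pipeline(matrix, network, RunConfig(seed=42))
print(f"screening kept {len(result.evidence)} edges "
      f"(SNR threshold {result.snr_threshold:.3f}); "
      f"{len(result.pre_merge)} edge modules -> {len(result.biclusters)} biclusters")

report = recovery_score(result.biclusters, truth)
print(f"recovery (mean best-match cell Jaccard over true modules): "
      f"{report.recovery:.3f}")
print(f"relevance (mean best match over found clusters):          "
      f"{report.relevance:.3f}")
for i, c in enumerate(result.biclusters[:5], start=1):
    print(f"  cluster {i}: {len(c.genes)} genes x {len(c.samples)} samples, "
          f"avg SNR {c.avg_snr:.3f}")
# A recovery near 1 means each planted gene x sample block was found almost
# exactly; the per-cluster SNR is the mean over genes of the standardized
# in-set vs out-of-set expression difference.
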