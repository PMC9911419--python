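"""Group edge-level sample sets into modules with the collapsed Gibbs sampler.

Thirty edges carry one of two planted sample-membership patterns plus flip
noise; the Bernoulli-mixture sampler, started from singleton labels, should
coalesce them into two components whose posterior sample sets match the
planted patterns.
"""
import numpy as np

from netbiclust.sampler import EdgeMembershipMatrix, GibbsConfig, run_gibbs

rng = np.random.default_rng(0)
n_samples, n_edges = 30, 30
pattern_a = np.zeros(n_samples, dtype=np.uint8)
pattern_a[:10] = 1
pattern_b = np.zeros(n_samples, dtype=np.uint8)
pattern_b[15:27] = 1

rows = []
for j in range(n_edges):
    base = pattern_a if j < 15 else pattern_b
    noisy = base ^ (rng.random(n_samples) < 0.05).astype(np.uint8)
    if noisy.sum() == 0:
        noisy = base.copy()
    rows.append(noisy)

x = EdgeMembershipMatrix(
    [(f"g{j}a", f"g{j}b") for j in range(n_edges)],
    [f"s{i:02d}" for i in range(n_samples)],
    np.array(rows),
)
cfg = GibbsConfig(K=n_edges, alpha=0.5, beta_over_k=1.0,
                  n_sweeps=300, n_burnin=150, seed=1)
res = run_gibbs(x, cfg, init=np.arange(n_edges))

labels = res.assignments
groups = {k: np.flatnonzero(labels == k) for k in np.unique(labels)}
print(f"{n_edges} edges coalesced into {len(groups)} components "
      f"(started from {n_edges} singleton labels)")
for k, members in groups.items():
    c1 = x.x[members].sum(axis=0)
    post = (c1 + cfg.alpha / 2) / (len(members) + cfg.alpha)
    samples = np.flatnonzero(post > 0.5)
    print(f"  component {k}: {len(members)} edges, "
          f"posterior sample set {samples.min()}..{samples.max()} "
          f"({len(samples)} samples)")
# Two components with sample ranges 0..9 and 15..26 mean the sampler
# recovered both planted membership patterns despite 5% bit-flip noise.
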