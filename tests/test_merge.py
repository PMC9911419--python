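"""Fisher overlap test, hierarchical bipartition, and iterative merging."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact

from netbiclust.data_io import Bicluster, ExpressionMatrix
from netbiclust.merge import (
    MergeRejection,
    bipartition_samples,
    fisher_overlap_test,
    iterative_merge,
    try_merge,
)
from netbiclust.simulate import SimulationSpec, generate_dataset
from netbiclust.snr import set_snr


def two_sided_fisher_oracle(n, na, nb, t):
    """Exact-rational enumeration of all hypergeometric tables."""
    lo, hi = max(0, na + nb - n), min(na, nb)
    probs = {x: Fraction(comb(na, x) * comb(n - na, nb - x), comb(n, nb)) for x in range(lo, hi + 1)}
    obs = probs[t]
    return float(sum(p for p in probs.values() if p <= obs))


def _bc(genes, samples):
    return Bicluster(frozenset(genes), frozenset(samples), 1.0)


class TestFisherOverlapTest:
    def test_disjoint_halves_hand_value(self):
        universe = [f"s{i}" for i in range(10)]
        a = _bc({"g"}, universe[:5])
        b = _bc({"h"}, universe[5:])
        assert fisher_overlap_test(a, b, universe) == pytest.approx(2 / 252, abs=1e-12)

    @pytest.mark.parametrize(
        "n,na,nb,t",
        [(10, 5, 5, 0), (10, 5, 5, 5), (12, 4, 7, 2), (8, 3, 3, 3), (11, 6, 5, 3),
         (9, 2, 7, 1), (12, 6, 6, 3)],
    )
    def test_matches_enumeration_and_scipy(self, n, na, nb, t):
        universe = [f"s{i}" for i in range(n)]
        a = _bc({"g"}, universe[:na])
        b = _bc({"h"}, universe[na - t:na - t + nb])
        p = fisher_overlap_test(a, b, universe)
        assert p == pytest.approx(two_sided_fisher_oracle(n, na, nb, t), abs=1e-10)
        table = [[t, na - t], [nb - t, n - na - nb + t]]
        assert p == pytest.approx(fisher_exact(table)[1], abs=1e-10)

    def test_symmetric(self):
        universe = [f"s{i}" for i in range(12)]
        a = _bc({"g"}, universe[:6])
        b = _bc({"h"}, universe[4:9])
        assert fisher_overlap_test(a, b, universe) == pytest.approx(
            fisher_overlap_test(b, a, universe)
        )

    def test_degenerate_universe_set_warns(self):
        universe = [f"s{i}" for i in range(6)]
        a = _bc({"g"}, universe[:3])
        b = _bc({"h"}, universe)
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_overlap_test(a, b, universe) == 1.0


class TestBipartitionSamples:
    def test_two_valued_gene_splits_cleanly(self):
        m = ExpressionMatrix(
            ["g"], [f"s{i}" for i in range(1, 7)],
            np.array([[5.0, 5.0, 5.0, 0.0, 0.0, 0.0]]),
        )
        parts = set(bipartition_samples(["g"], m))
        assert parts == {frozenset({"s1", "s2", "s3"}), frozenset({"s4", "s5", "s6"})}

    def test_recovers_planted_block(self):
        rng = np.random.default_rng(8)
        n = 100
        v = rng.normal(size=(2, n))
        v[:, :30] += 5
        m = ExpressionMatrix(["a", "b"], [f"s{i:03d}" for i in range(n)], v)
        parts = bipartition_samples(["a", "b"], m)
        block = {f"s{i:03d}" for i in range(30)}
        assert block in [set(p) for p in parts]

    def test_column_permutation_invariant_as_sets(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(2, 12))
        v[:, :5] += 4
        ids = [f"s{i}" for i in range(12)]
        m1 = ExpressionMatrix(["a", "b"], ids, v)
        perm = rng.permutation(12)
        m2 = ExpressionMatrix(["a", "b"], [ids[i] for i in perm], v[:, perm])
        assert set(bipartition_samples(["a", "b"], m1)) == set(
            bipartition_samples(["a", "b"], m2)
        )

    def test_identical_profiles_error(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c", "d"], np.ones((1, 4)))
        with pytest.raises(ValueError, match="identical"):
            bipartition_samples(["g"], m)


@pytest.fixture(scope="module")
def planted_two_modules():
    spec = SimulationSpec(
        n_genes=80, n_samples=80, n_modules=2, in_mean=5.0,
        fixed_module_size=(12, 10), seed=10,
    )
    matrix, modules = generate_dataset(spec)
    return matrix, modules


class TestTryMerge:
    def test_cap_steers_candidate_to_minority_branch(self):
        # the natural Ward split isolates 120 elevated samples (>= 110 cap);
        # both branches share one SNR, so the under-cap complement is taken
        rng = np.random.default_rng(0)
        n = 200
        v = rng.normal(size=(2, n))
        v[:, :120] += 5
        m = ExpressionMatrix(["a", "b"], [f"s{i:03d}" for i in range(n)], v)
        a = Bicluster(frozenset({"a"}), frozenset(m.sample_ids[:90]), 1.0)
        b = Bicluster(frozenset({"b"}), frozenset(m.sample_ids[30:120]), 1.0)
        out = try_merge(a, b, m, snr_threshold=0.0, fisher_alpha=0.05, direction="similar")
        assert isinstance(out, Bicluster)
        assert len(out.samples) < 0.55 * n
        assert out.samples == frozenset(m.sample_ids[120:])

    def test_split_module_halves_remerge(self, planted_two_modules):
        matrix, modules = planted_two_modules
        mod = modules[0]
        genes = sorted(mod.genes)
        a = Bicluster(frozenset(genes[:5]), mod.samples, 1.0)
        b = Bicluster(frozenset(genes[5:]), mod.samples, 1.0)
        out = try_merge(a, b, matrix, snr_threshold=0.1, direction="similar")
        assert isinstance(out, Bicluster)
        assert out.genes == mod.genes
        assert out.samples == mod.samples

    def test_disjoint_modules_rejected_at_fisher(self, planted_two_modules):
        matrix, modules = planted_two_modules
        m0, m1 = modules
        a = Bicluster(m0.genes, m0.samples, 1.0)
        b = Bicluster(m1.genes, m1.samples - m0.samples, 1.0)
        out = try_merge(a, b, matrix, snr_threshold=0.1, direction="similar")
        assert isinstance(out, MergeRejection)
        assert out.reason == "fisher"


class TestIterativeMerge:
    def test_single_cluster_unchanged(self, planted_two_modules):
        matrix, modules = planted_two_modules
        c = Bicluster(modules[0].genes, modules[0].samples, 2.0)
        out, log = iterative_merge([c], matrix, snr_threshold=0.1)
        assert out == [c]

    def test_three_fragments_converge_to_one(self, planted_two_modules):
        matrix, modules = planted_two_modules
        mod = modules[0]
        genes = sorted(mod.genes)
        frags = [
            Bicluster(frozenset(genes[i::3]), mod.samples, 1.0) for i in range(3)
        ]
        out, _ = iterative_merge(frags, matrix, snr_threshold=0.1, direction="similar")
        assert len(out) == 1
        assert out[0].genes == mod.genes

    def test_separated_modules_stay_separate(self, planted_two_modules):
        matrix, modules = planted_two_modules
        clusters = [
            Bicluster(mo.genes, mo.samples, set_snr(mo.genes, mo.samples, matrix))
            for mo in modules
        ]
        out, _ = iterative_merge(clusters, matrix, snr_threshold=0.1, direction="similar")
        assert len(out) == 2

    def test_outputs_satisfy_constraints(self, planted_two_modules):
        matrix, modules = planted_two_modules
        mod = modules[0]
        genes = sorted(mod.genes)
        frags = [
            Bicluster(frozenset(genes[:6]), mod.samples, 1.0),
            Bicluster(frozenset(genes[6:]), mod.samples, 1.0),
            Bicluster(modules[1].genes, modules[1].samples, 1.0),
        ]
        thr = 0.1
        out, _ = iterative_merge(frags, matrix, snr_threshold=thr)
        for c in out:
            assert len(c.samples) < 0.55 * matrix.n_samples
            assert c.avg_snr > thr
            recomputed = set_snr(c.genes, c.samples, matrix)
            assert recomputed > thr
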