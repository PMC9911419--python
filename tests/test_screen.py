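"""RRHO screening: hypergeometric oracle, SNR properties, grid optimum."""
import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from netbiclust.data_io import ExpressionMatrix, GeneNetwork
from netbiclust.screen import (
    ScreenConfig,
    overlap_pvalue,
    preliminary_snr_threshold,
    retained_network,
    rrho_edge,
    screen_network_edges,
)
from netbiclust.snr import gene_snr, set_snr, snr_from_values


def overlap_pvalue_oracle(n, a, b, o):
    """P[|A ∩ B| >= o] by exhaustive enumeration of all size-b subsets."""
    items = range(n)
    a_set = set(range(a))
    hits = total = 0
    for subset in itertools.combinations(items, b):
        total += 1
        hits += len(a_set & set(subset)) >= o
    return Fraction(hits, total)


class TestOverlapPvalue:
    @pytest.mark.parametrize(
        "n,a,b,o",
        [(10, 5, 5, 4), (8, 3, 5, 2), (12, 6, 4, 0), (12, 6, 4, 4), (7, 7, 3, 3),
         (9, 4, 4, 1), (11, 5, 6, 3)],
    )
    def test_matches_exhaustive_enumeration(self, n, a, b, o):
        assert overlap_pvalue(n, a, b, o) == pytest.approx(
            float(overlap_pvalue_oracle(n, a, b, o)), abs=1e-12
        )

    def test_hand_value(self):
        assert overlap_pvalue(10, 5, 5, 4) == pytest.approx(26 / 252, abs=1e-12)

    def test_zero_overlap_is_certain(self):
        assert overlap_pvalue(10, 4, 7, 0) == 1.0

    def test_forced_full_overlap_is_certain(self):
        assert overlap_pvalue(6, 6, 6, 6) == pytest.approx(1.0)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            overlap_pvalue(10, 5, 5, 6)
        with pytest.raises(ValueError):
            overlap_pvalue(10, 11, 5, 1)


class TestGeneSnr:
    def test_hand_example(self):
        v = np.array([3.0, 1.0, 1.0, -1.0])
        mask = np.array([True, True, False, False])
        assert snr_from_values(v, mask) == pytest.approx(1.0)

    def test_identical_distributions_give_zero(self):
        v = np.array([0.0, 2.0, 2.0, 0.0])
        mask = np.array([True, True, False, False])
        assert snr_from_values(v, mask) == pytest.approx(0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        values=st.lists(st.floats(-50, 50), min_size=4, max_size=12),
        scale=st.floats(0.01, 100),
        shift=st.floats(-100, 100),
    )
    def test_positive_affine_invariance(self, values, scale, shift):
        v = np.asarray(values)
        k = len(v) // 2
        mask = np.zeros(len(v), dtype=bool)
        mask[:k] = True
        base = snr_from_values(v, mask)
        mapped = snr_from_values(scale * v + shift, mask)
        assert mapped == pytest.approx(base, rel=1e-6, abs=1e-9)

    def test_complement_and_sign_flip_symmetry(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=10)
        mask = np.zeros(10, dtype=bool)
        mask[:4] = True
        assert snr_from_values(v, mask) == pytest.approx(snr_from_values(-v, ~mask))

    def test_degenerate_set_errors(self, tiny_matrix):
        with pytest.raises(ValueError):
            gene_snr("g1", [], tiny_matrix)
        with pytest.raises(ValueError):
            gene_snr("g1", tiny_matrix.sample_ids, tiny_matrix)

    def test_set_snr_is_mean_and_symmetric(self, tiny_matrix):
        p = ["s1", "s2", "s3"]
        a = gene_snr("g1", p, tiny_matrix)
        b = gene_snr("g2", p, tiny_matrix)
        assert set_snr(["g1", "g2"], p, tiny_matrix) == pytest.approx((a + b) / 2)
        assert set_snr(["g2", "g1"], p, tiny_matrix) == pytest.approx(
            set_snr(["g1", "g2"], p, tiny_matrix)
        )


def rrho_brute_force(v1, v2, tails=("high", "low")):
    """Independent grid search: all prefix pairs, set arithmetic, scipy sf.

    Returns the minimal p and every (tail, prefix-intersection) whose p ties
    the minimum to within float tolerance; tie-breaking among exactly-tied
    grid cells is an implementation detail the oracle does not pin down.
    """
    n = len(v1)
    cells = []
    for tail in tails:
        sign = -1 if tail == "high" else 1
        oa = np.argsort(sign * v1, kind="stable")
        ob = np.argsort(sign * v2, kind="stable")
        for i in range(2, n - 1):
            for j in range(2, n - 1):
                o = len(set(oa[:i]) & set(ob[:j]))
                p = float(hypergeom.sf(o - 1, n, i, j))
                cells.append((p, tail, frozenset(oa[:i]) & frozenset(ob[:j])))
    p_min = min(c[0] for c in cells)
    ties = [(t, o) for p, t, o in cells if p <= p_min * (1 + 1e-9)]
    return p_min, ties


class TestRrhoEdge:
    def _matrix(self, v1, v2):
        n = len(v1)
        return ExpressionMatrix(
            ["g1", "g2"], [f"s{i}" for i in range(n)], np.array([v1, v2], dtype=float)
        )

    def test_identical_genes_match_brute_force(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=8)
        m = self._matrix(v, v + 0.0)
        ev = rrho_edge("g1", "g2", m)
        p, ties = rrho_brute_force(v, v)
        assert ev.p_min == pytest.approx(p, rel=1e-9)
        assert any({f"s{k}" for k in o} == set(ev.samples) for _, o in ties)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_pairs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        v1, v2 = rng.normal(size=(2, 8))
        m = self._matrix(v1, v2)
        ev = rrho_edge("g1", "g2", m)
        p, ties = rrho_brute_force(v1, v2)
        assert ev.p_min == pytest.approx(p, rel=1e-9)
        short = {"concordant-high": "high", "concordant-low": "low"}[ev.direction]
        assert any(
            t == short and {f"s{k}" for k in o} == set(ev.samples) for t, o in ties
        )

    def test_anti_correlated_pair_high_tail_only(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=8)
        m = self._matrix(v, -v)
        ev = rrho_edge("g1", "g2", m, ScreenConfig(tails="high"))
        p, _ = rrho_brute_force(v, -v, tails=("high",))
        assert ev.p_min == pytest.approx(p, rel=1e-9)
        assert ev.direction == "concordant-high"

    def test_symmetric_in_gene_order(self):
        rng = np.random.default_rng(3)
        v1, v2 = rng.normal(size=(2, 12))
        m = self._matrix(v1, v2)
        e12 = rrho_edge("g1", "g2", m)
        e21 = rrho_edge("g2", "g1", m)
        assert e12.p_min == pytest.approx(e21.p_min)
        assert e12.samples == e21.samples

    def test_correlated_beats_independent_stochastically(self):
        rng = np.random.default_rng(4)
        p_corr, p_ind = [], []
        for _ in range(40):
            g1 = rng.normal(size=50)
            m = self._matrix(g1, g1 + 0.3 * rng.normal(size=50))
            p_corr.append(rrho_edge("g1", "g2", m).p_min)
            m = self._matrix(g1, rng.normal(size=50))
            p_ind.append(rrho_edge("g1", "g2", m).p_min)
        assert np.median(np.log(p_corr)) < np.median(np.log(p_ind)) - 5


class TestScreening:
    def test_vacuous_thresholds_keep_everything(self, small_planted):
        _, matrix, _, network = small_planted
        from netbiclust.data_io import normalize_per_gene, prune_isolated_genes

        net, m = prune_isolated_genes(network, normalize_per_gene(matrix))
        cfg = ScreenConfig(p_threshold=1.0, snr_threshold=0.0)
        kept, thr = screen_network_edges(m, net, cfg)
        assert len(kept) == net.n_edges

    def test_impossible_threshold_errors(self, small_planted):
        _, matrix, _, network = small_planted
        from netbiclust.data_io import normalize_per_gene, prune_isolated_genes

        net, m = prune_isolated_genes(network, normalize_per_gene(matrix))
        cfg = ScreenConfig(p_threshold=1.0, snr_threshold=1e9)
        with pytest.raises(ValueError, match="no edge survived"):
            screen_network_edges(m, net, cfg)

    def test_retained_evidence_satisfies_filters(self, small_planted):
        _, matrix, _, network = small_planted
        from netbiclust.data_io import normalize_per_gene, prune_isolated_genes

        net, m = prune_isolated_genes(network, normalize_per_gene(matrix))
        kept, thr = screen_network_edges(m, net, ScreenConfig())
        assert kept
        for e in kept:
            assert e.p_min <= 0.01
            assert e.snr > thr
            # snr recomputable from the matrix
            recomputed = 0.5 * (
                gene_snr(e.gene_a, e.samples, m) + gene_snr(e.gene_b, e.samples, m)
            )
            assert e.snr == pytest.approx(recomputed, abs=1e-9)

    def test_planted_pairs_only_survive(self):
        # 2 co-expressed pairs + 2 unrelated pairs; only the planted edges pass
        rng = np.random.default_rng(0)
        n = 60
        values = rng.normal(size=(8, n))
        block = np.zeros(n, dtype=bool)
        block[:20] = True
        for g in (0, 1, 2, 3):
            values[g, block] += 5.0
        m = ExpressionMatrix([f"g{i}" for i in range(8)], [f"s{i}" for i in range(n)], values)
        net = GeneNetwork.from_edges([("g0", "g1"), ("g2", "g3"), ("g4", "g5"), ("g6", "g7")])
        kept, _ = screen_network_edges(m, net, ScreenConfig())
        kept_pairs = {frozenset((e.gene_a, e.gene_b)) for e in kept}
        assert kept_pairs == {frozenset({"g0", "g1"}), frozenset({"g2", "g3"})}

    def test_preliminary_threshold_positive_and_below_planted(self, small_planted):
        _, matrix, modules, network = small_planted
        from netbiclust.data_io import normalize_per_gene, prune_isolated_genes

        net, m = prune_isolated_genes(network, normalize_per_gene(matrix))
        thr = preliminary_snr_threshold(m, net)
        assert thr > 0
        planted_snr = min(
            set_snr(mo.genes & set(m.gene_ids), mo.samples, m) for mo in modules
        )
        assert thr < planted_snr
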