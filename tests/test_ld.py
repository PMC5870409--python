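"""Two-locus counting, EM haplotype frequencies, LD statistics, D' CIs and
Gabriel blocks."""

import itertools

import numpy as np
import pytest

from hbbhaplo.ld import (
    GabrielParams,
    HaplotypePanel,
    TwoLocusCounts,
    block_haplotype_freqs,
    dprime_ci,
    em_haplotype_freq,
    gabriel_blocks,
    ld_pair,
    two_locus_counts,
)
from hbbhaplo.synthetic import RegionSpec, simulate_region_panel


def make_panel(rows, positions=None, phased=True):
    data = np.asarray(rows, dtype=np.int8)
    m = data.shape[1]
    return HaplotypePanel(
        markers=[f"m{i}" for i in range(m)],
        positions=positions if positions is not None else np.arange(1, m + 1) * 100,
        data=data,
        phased=phased,
    )


class TestTwoLocusCounts:
    def test_phased_counting(self):
        panel = make_panel([[0, 0], [0, 0], [1, 1], [1, 1]])
        counts = two_locus_counts(panel, "m0", "m1")
        assert counts.haplotypes == (2, 0, 0, 2)

    def test_missing_chromosome_excluded(self):
        panel = make_panel([[0, 0], [-1, 0], [1, 1]])
        counts = two_locus_counts(panel, 0, 1)
        assert counts.total == 2

    def test_unknown_marker(self):
        panel = make_panel([[0, 0]])
        with pytest.raises(KeyError):
            two_locus_counts(panel, "m0", "nope")

    def test_matches_brute_force_tally(self, rng):
        data = rng.integers(0, 2, size=(60, 4))
        panel = make_panel(data)
        for i, j in itertools.combinations(range(4), 2):
            counts = two_locus_counts(panel, i, j)
            expect = [0, 0, 0, 0]
            for row in data:
                expect[2 * row[i] + row[j]] += 1
            assert counts.haplotypes == tuple(expect)

    def test_unphased_cross_table(self):
        panel = make_panel([[0, 2], [1, 1], [2, 0]], phased=False)
        counts = two_locus_counts(panel, 0, 1)
        assert counts.genotype_table[0, 2] == 1
        assert counts.genotype_table[1, 1] == 1
        assert counts.genotype_table[2, 0] == 1


def grid_search_ml(table: np.ndarray, step: float = 1e-4):
    """Profile the unphased likelihood over p11 at fixed observed margins."""
    from hbbhaplo.ld import _unphased_loglik

    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    pA = (row[1] + 2 * row[2]) / (2 * n)
    pB = (col[1] + 2 * col[2]) / (2 * n)
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    best, best_ll = None, -np.inf
    for p11 in np.arange(lo, hi + step / 2, step):
        freqs = np.array([
            1 - pA - pB + p11, pB - p11, pA - p11, p11
        ])
        if freqs.min() < -1e-12:
            continue
        ll = _unphased_loglik(np.clip(freqs, 1e-12, None), table)
        if ll > best_ll:
            best, best_ll = freqs, ll
    return best


class TestEM:
    def test_no_double_heterozygotes_is_closed_form(self):
        table = np.array([[3, 0, 0], [0, 0, 0], [0, 0, 2]])
        res = em_haplotype_freq(table)
        assert res.freqs == pytest.approx((0.6, 0.0, 0.0, 0.4))

    def test_double_het_resolved_to_cis(self):
        table = np.zeros((3, 3), dtype=int)
        table[0, 0] = 2  # 00/00
        table[2, 2] = 2  # 11/11
        table[1, 1] = 1  # double heterozygote
        res = em_haplotype_freq(table)
        assert res.freqs[0] > 0.4 and res.freqs[3] > 0.4
        oracle = grid_search_ml(table)
        assert np.allclose(res.freqs, oracle, atol=2e-4)

    def test_lone_double_het_unidentifiable(self):
        table = np.zeros((3, 3), dtype=int)
        table[1, 1] = 1
        res = em_haplotype_freq(table)
        assert res.unidentifiable
        assert res.freqs == pytest.approx((0.25, 0.25, 0.25, 0.25))

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            em_haplotype_freq(np.zeros((3, 3)))

    def test_frequencies_sum_to_one_and_match_grid_oracle(self, rng):
        for _ in range(20):
            table = rng.integers(0, 8, size=(3, 3))
            if table.sum() == 0 or table.sum() == table[1, 1]:
                continue
            res = em_haplotype_freq(table)
            assert sum(res.freqs) == pytest.approx(1.0)
            oracle = grid_search_ml(table)
            assert np.allclose(res.freqs, oracle, atol=2e-4)

    def test_loglik_nondecreasing(self):
        table = np.array([[5, 2, 1], [3, 4, 2], [1, 2, 5]])
        lls = [
            em_haplotype_freq(table, tol=0.0, max_iter=k).log_likelihood
            for k in range(1, 15)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


class TestLdPair:
    def test_independence(self):
        stats = ld_pair((0.25, 0.25, 0.25, 0.25))
        assert stats.D == pytest.approx(0.0)
        assert stats.r_squared == pytest.approx(0.0)

    def test_complete_ld(self):
        stats = ld_pair((0.5, 0.0, 0.0, 0.5))
        assert stats.d_prime == 1.0 and stats.r_squared == 1.0

    def test_closed_form_example(self):
        # pA=0.2, pB=0.4, p11=0.1 -> p10=0.1, p01=0.3, p00=0.5
        stats = ld_pair((0.5, 0.3, 0.1, 0.1))
        assert stats.D == pytest.approx(0.02)
        assert stats.d_prime == pytest.approx(0.02 / 0.12)
        assert stats.r_squared == pytest.approx(0.0004 / 0.0384)

    def test_monomorphic_flagged_undefined(self):
        stats = ld_pair((0.5, 0.5, 0.0, 0.0))
        assert not stats.defined and stats.d_prime is None

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError):
            ld_pair((0.5, 0.5, 0.5, 0.5))

    def test_bounds_and_r2_one_implies_dprime_one(self, rng):
        for _ in range(200):
            f = rng.dirichlet(np.ones(4))
            stats = ld_pair(f)
            if not stats.defined:
                continue
            assert 0.0 <= stats.d_prime <= 1.0
            assert 0.0 <= stats.r_squared <= 1.0
            if stats.r_squared > 1 - 1e-12:
                assert stats.d_prime == pytest.approx(1.0)


class TestDprimeCI:
    def test_complete_ld_large_n_concentrates_at_one(self):
        counts = TwoLocusCounts(True, haplotypes=(500, 0, 0, 500))
        lo, hi = dprime_ci(counts)
        assert lo >= 0.98 and hi == 1.0

    def test_tiny_sample_is_wide(self):
        counts = TwoLocusCounts(True, haplotypes=(2, 0, 0, 2))
        lo, hi = dprime_ci(counts)
        assert lo < 0.7 and hi > 0.9

    def test_independence_large_n_upper_below_point_nine(self):
        counts = TwoLocusCounts(True, haplotypes=(250, 250, 250, 250))
        lo, hi = dprime_ci(counts)
        assert hi < 0.9 and lo == 0.0

    def test_monomorphic_marker_rejected(self):
        with pytest.raises(ValueError):
            dprime_ci(TwoLocusCounts(True, haplotypes=(10, 0, 10, 0)))

    def test_unphased_counts_supported(self):
        table = np.array([[30, 0, 0], [0, 5, 0], [0, 0, 30]])
        lo, hi = dprime_ci(TwoLocusCounts(False, genotype_table=table))
        assert lo >= 0.9


def block_oracle(panel, params=GabrielParams()):
    """Exhaustive re-application of the block rule over all spans, using the
    public CI primitive directly."""
    m = panel.n_markers
    pair_strong = {}
    for i, j in itertools.combinations(range(m), 2):
        if panel.maf(i) == 0 or panel.maf(j) == 0:
            continue
        lo, hi = dprime_ci(two_locus_counts(panel, i, j), params.ci_grid)
        pair_strong[(i, j)] = lo >= params.strong_low and hi >= params.strong_high
    spans = []
    for a in range(m - 1):
        for b in range(a + 1, m):
            pairs = [pair_strong[(i, j)]
                     for i, j in itertools.combinations(range(a, b + 1), 2)
                     if (i, j) in pair_strong]
            if pairs and sum(pairs) / len(pairs) >= params.strong_fraction:
                spans.append((a, b))
    spans.sort(key=lambda ab: (-(ab[1] - ab[0]), ab[0]))
    chosen = []
    for a, b in spans:
        if all(b < ca or a > cb for ca, cb in chosen):
            chosen.append((a, b))
    return sorted(chosen)


class TestGabrielBlocks:
    def test_single_founder_block_spans_all_markers(self):
        spec = RegionSpec(n_markers=5, core_index=0, n_individuals=500, seed=2)
        f = np.array([[0, 1, 0, 1, 0], [1, 0, 1, 0, 1]])
        panel = simulate_region_panel(spec, founders=[f])
        blocks = gabriel_blocks(panel)
        assert [(b.start, b.end) for b in blocks] == [(0, 4)]

    def test_independent_markers_give_no_blocks(self):
        spec = RegionSpec(n_markers=5, core_index=0,
                          recomb_breakpoints=(1, 2, 3, 4),
                          n_individuals=1000, seed=4)
        founders = [np.array([[0], [1]]) for _ in range(5)]
        panel = simulate_region_panel(spec, founders=founders)
        assert gabriel_blocks(panel) == []

    def test_mixed_panel_matches_exhaustive_span_oracle(self):
        spec = RegionSpec(n_markers=5, core_index=0, recomb_breakpoints=(3,),
                          n_individuals=400, seed=8)
        f1 = np.array([[0, 1, 0], [1, 0, 1]])
        f2 = np.array([[0, 0], [1, 1]])
        panel = simulate_region_panel(spec, founders=[f1, f2])
        blocks = gabriel_blocks(panel)
        assert [(b.start, b.end) for b in blocks] == block_oracle(panel)

    def test_invariant_to_chromosome_order(self, rng):
        spec = RegionSpec(n_markers=6, core_index=0, recomb_breakpoints=(3,),
                          n_individuals=300, seed=5)
        panel = simulate_region_panel(spec)
        perm = rng.permutation(panel.n_chromosomes)
        shuffled = HaplotypePanel(panel.markers, panel.positions.copy(),
                                  panel.data[perm], phased=True)
        a = [(b.start, b.end) for b in gabriel_blocks(panel)]
        b = [(b.start, b.end) for b in gabriel_blocks(shuffled)]
        assert a == b

    def test_single_marker_panel_empty(self):
        panel = make_panel([[0], [1]])
        assert gabriel_blocks(panel) == []


class TestBlockHaplotypeFreqs:
    def test_identical_chromosomes(self):
        spec = RegionSpec(n_markers=4, core_index=0,
                          founder_haplotypes_per_block=1, n_individuals=10,
                          seed=1)
        panel = simulate_region_panel(spec)
        blocks = gabriel_blocks(panel) or [
            type("B", (), {"start": 0, "end": 3})()
        ]
        from hbbhaplo.ld import HaploBlock
        freqs = block_haplotype_freqs(panel, HaploBlock(0, 3, tuple(panel.markers)))
        assert len(freqs) == 1 and list(freqs.values()) == [1.0]

    def test_two_equifrequent_founders(self):
        spec = RegionSpec(n_markers=3, core_index=0, n_individuals=2000, seed=6)
        f = np.array([[0, 1, 0], [1, 0, 1]])
        panel = simulate_region_panel(spec, founders=[f])
        from hbbhaplo.ld import HaploBlock
        freqs = block_haplotype_freqs(panel, HaploBlock(0, 2, tuple(panel.markers)))
        assert set(freqs) == {"010", "101"}
        se = np.sqrt(0.25 / panel.n_chromosomes)
        assert abs(freqs["010"] - 0.5) < 3 * se

    def test_proportions_sum_to_one(self, rng):
        panel = make_panel(rng.integers(0, 2, size=(40, 5)))
        from hbbhaplo.ld import HaploBlock
        freqs = block_haplotype_freqs(panel, HaploBlock(1, 4, tuple(panel.markers[1:5])))
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_unphased_input_rejected(self):
        panel = make_panel([[0, 1], [2, 1]], phased=False)
        from hbbhaplo.ld import HaploBlock
        with pytest.raises(ValueError, match="phased"):
            block_haplotype_freqs(panel, HaploBlock(0, 1, ("m0", "m1")))
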