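import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bgsinfer import (
    SFS,
    MaskSet,
    abc_stat_vector,
    compute_sfs,
    scale_zero_class,
    thin_snps,
    window_stats,
)
from bgsinfer.sumstats import nucleotide_diversity, thin_sample

from conftest import random_sample


def pairwise_hamming_mean(H: np.ndarray) -> float:
    """Independent oracle: mean pairwise Hamming distance over haplotypes."""
    n = H.shape[0]
    tot = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            tot += np.sum(H[i] != H[j])
    return tot / (n * (n - 1) / 2)


class TestSfs:
    def test_two_site_tally(self, rng):
        s = random_sample(rng, n_hap=20, n_sites=0)
        H = np.zeros((20, 2), dtype=np.uint8)
        H[:1, 0] = 1
        H[:10, 1] = 1
        s.haplotypes = H
        s.positions = np.array([10, 20])
        s.chrom = np.zeros(2, dtype=np.int32)
        sfs = compute_sfs(s)
        assert sfs.counts[1] == 1 and sfs.counts[10] == 1
        assert sfs.counts[2:10].sum() == 0 and sfs.counts[11:].sum() == 0
        assert sfs.counts[0] == 100_000 - 2

    def test_total_sites_equals_unmasked_length(self, rng):
        s = random_sample(rng, n_hap=10, n_sites=40)
        sfs = compute_sfs(s)
        assert sfs.total_sites == 100_000

    def test_mask_excludes_sites_and_length(self, rng):
        s = random_sample(rng, n_hap=10, n_sites=40)
        mask = MaskSet(intervals={0: ((0, 50_000),)})
        sfs = compute_sfs(s, mask=mask)
        n_in_mask = int(np.sum(s.positions < 50_000))
        assert sfs.n_segregating == 40 - n_in_mask
        assert sfs.total_sites == 50_000

    def test_full_mask_rejected(self, rng):
        s = random_sample(rng, n_hap=10, n_sites=5)
        with pytest.raises(ValueError):
            compute_sfs(s, mask=MaskSet(intervals={0: ((0, 100_000),)}))

    def test_fold_matches_direct_folding(self, rng):
        s = random_sample(rng, n_hap=10, n_sites=60)
        unfolded = compute_sfs(s)
        folded = compute_sfs(s, fold=True)
        assert folded.folded
        for b in range(1, 6):
            expect = unfolded.counts[b] + (unfolded.counts[10 - b] if b != 10 - b else 0)
            assert folded.counts[b] == expect
        assert folded.total_sites == unfolded.total_sites

    def test_neutral_sfs_follows_one_over_b(self):
        # standard neutral expectation xi_b proportional to 1/b, checked
        # against the coalescent engine
        from bgsinfer import equilibrium, sfs_counts_replicates

        counts = sfs_counts_replicates(equilibrium(5000), 5e6, 20, 1e-8, 1e-8, 10, seed=77)
        tot = counts.sum(axis=0).astype(float)
        b = np.arange(1, 20)
        expect = (1 / b) / (1 / b).sum() * tot.sum()
        # loose chi-square-style check: each class within 5 sigma
        assert np.all(np.abs(tot - expect) < 5 * np.sqrt(expect) + 5)


class TestThinning:
    def test_hand_traced_greedy_rule(self):
        kept = thin_snps(np.array([100, 4000, 5100, 9000, 10200]), 5000)
        assert list(kept) == [0, 2, 4]

    def test_single_and_zero_gap(self):
        assert list(thin_snps(np.array([42]), 5000)) == [0]
        assert list(thin_snps(np.arange(10), 0)) == list(range(10))

    @given(
        pos=st.lists(st.integers(0, 10**6), min_size=1, max_size=80, unique=True),
        gap=st.integers(1, 10**5),
    )
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_gap_respected(self, pos, gap):
        p = np.sort(np.array(pos))
        kept = thin_snps(p, gap)
        assert kept[0] == 0  # first SNP always kept
        assert np.all(np.diff(p[kept]) >= gap)
        again = thin_snps(p[kept], gap)
        assert list(again) == list(range(len(kept)))

    def test_scale_zero_class(self):
        sfs = SFS(counts=np.array([1_000_000, 50, 30, 0, 0]), n_hap=4)
        scaled = scale_zero_class(sfs, 0.01)
        assert scaled.counts[0] == 10_000
        assert list(scaled.counts[1:]) == [50, 30, 0, 0]
        ident = scale_zero_class(sfs, 1.0)
        assert list(ident.counts) == list(sfs.counts)
        with pytest.raises(ValueError):
            scale_zero_class(sfs, 1.5)

    def test_thin_sample_reports_kept_fraction(self, rng):
        s = random_sample(rng, n_hap=10, n_sites=50)
        thinned, frac = thin_sample(s, 10_000)
        assert frac == pytest.approx(thinned.n_sites / 50)
        assert np.all(np.diff(thinned.positions) >= 10_000)


class TestWindowStats:
    def test_pi_hand_example(self, rng):
        # n=4, derived counts (1, 2): pi = 2*1*3/12 + 2*2*2/12 = 7/6
        s = random_sample(rng, n_hap=4, n_sites=0)
        H = np.zeros((4, 2), dtype=np.uint8)
        H[0, 0] = 1
        H[:2, 1] = 1
        s.haplotypes, s.positions, s.chrom = H, np.array([5, 10]), np.zeros(2, np.int32)
        [w] = window_stats(s, [(0, 0, 100_000)])
        assert w.pi * 100_000 == pytest.approx(7 / 6)

    def test_watterson_hand_example(self, rng):
        # n=4, S=7: theta_W = 7 / (1 + 1/2 + 1/3)
        s = random_sample(rng, n_hap=4, n_sites=7)
        [w] = window_stats(s, [(0, 0, 100_000)])
        assert w.theta_w * 100_000 == pytest.approx(7 / (11 / 6))
        assert w.n_snps == 7

    @given(
        H=arrays(np.uint8, (8, 12), elements=st.integers(0, 1)),
    )
    @settings(max_examples=40, deadline=None)
    def test_pi_equals_mean_pairwise_hamming(self, H):
        counts = H.sum(axis=0)
        keep = (counts > 0) & (counts < 8)
        H = H[:, keep]
        assert nucleotide_diversity(H.sum(axis=0), 8) == pytest.approx(
            pairwise_hamming_mean(H) if H.shape[1] else 0.0
        )

    def test_empty_window_flags_missing(self, rng):
        s = random_sample(rng, n_hap=10, n_sites=5, chrom_lengths=(1000,))
        s.positions = np.arange(5)  # all in [0, 5)
        [w] = window_stats(s, [(0, 500, 1000)])
        assert w.n_snps == 0 and w.pi == 0.0
        assert math.isnan(w.tajima_d) and math.isnan(w.mean_r2)

    def test_monomorphic_window_identical_haplotypes(self, rng):
        s = random_sample(rng, n_hap=6, n_sites=0, chrom_lengths=(1000,))
        s.haplotypes = np.zeros((6, 0), dtype=np.uint8)
        s.positions = np.zeros(0, dtype=np.int64)
        s.chrom = np.zeros(0, dtype=np.int32)
        [w] = window_stats(s, [(0, 0, 1000)])
        assert w.hap_diversity == 0.0

    def test_perfect_ld_r2_one(self, rng):
        s = random_sample(rng, n_hap=6, n_sites=0, chrom_lengths=(1000,))
        H = np.zeros((6, 2), dtype=np.uint8)
        H[:3, 0] = 1
        H[:3, 1] = 1  # identical columns: r2 = 1, D' = 1
        s.haplotypes, s.positions, s.chrom = H, np.array([10, 20]), np.zeros(2, np.int32)
        [w] = window_stats(s, [(0, 0, 1000)])
        assert w.mean_r2 == pytest.approx(1.0)
        assert w.mean_dprime == pytest.approx(1.0)

    def test_tajima_d_near_zero_at_neutral_equilibrium(self):
        from bgsinfer import equilibrium, run_neutral_coalescent

        ds = []
        for seed in range(60):
            s = run_neutral_coalescent(equilibrium(5000), 3e5, 20, 1e-8, 1e-8, seed + 1)
            [w] = window_stats(s, [(0, 0, 300_000)])
            if not math.isnan(w.tajima_d):
                ds.append(w.tajima_d)
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds)) < 3 * se + 0.05


class TestAbcVector:
    def test_identical_windows_zero_variance(self, rng):
        s = random_sample(rng, n_hap=10, n_sites=12, chrom_lengths=(500, 500))
        ws = window_stats(s, [(0, 0, 500), (0, 0, 500)])
        v = abc_stat_vector(ws)
        assert v.shape == (22,)
        assert np.allclose(v[11:], 0.0)

    def test_permutation_invariance(self, rng):
        s = random_sample(rng, n_hap=10, n_sites=40, chrom_lengths=(400, 400, 400))
        wins = [(c, 0, 400) for c in range(3)]
        v1 = abc_stat_vector(window_stats(s, wins))
        v2 = abc_stat_vector(window_stats(s, wins[::-1]))
        assert np.allclose(v1, v2)

    def test_requires_two_windows(self, rng):
        s = random_sample(rng, n_hap=10, n_sites=10)
        with pytest.raises(ValueError):
            abc_stat_vector(window_stats(s, [(0, 0, 100_000)]))

    def test_variances_nonnegative(self, rng):
        s = random_sample(rng, n_hap=10, n_sites=60, chrom_lengths=(300, 300, 300, 300))
        v = abc_stat_vector(window_stats(s, [(c, 0, 300) for c in range(4)]))
        assert np.all(v[11:] >= 0)
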