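"""Forward Wright-Fisher engine and neutral coalescent engine checks."""

import numpy as np
import pytest
from scipy import stats as sps

from bgsinfer import (
    DiscreteDFE,
    Locus,
    build_genome_layout,
    equilibrium,
    named_dfe,
    run_forward,
    run_neutral_coalescent,
    segregating_sites_replicates,
    unlinked_loci_sample,
)
from bgsinfer.genomes import Demography, Epoch
from bgsinfer.sumstats import nucleotide_diversity


class TestForwardBasics:
    def test_zero_mutation_rate_gives_no_sites(self):
        s = run_forward([Locus(10_000, 1e-7)], None, equilibrium(100), mu=0.0,
                        n_sample=5, seed=1)
        assert s.n_sites == 0

    def test_same_seed_bit_identical(self):
        kw = dict(mu=5e-7, n_sample=5, seed=77)
        a = run_forward([Locus(5_000, 1e-7)], None, equilibrium(100), **kw)
        b = run_forward([Locus(5_000, 1e-7)], None, equilibrium(100), **kw)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)

    def test_positions_strictly_increasing_per_chromosome(self):
        s = run_forward([Locus(2_000, 1e-7), Locus(2_000, 1e-7)], None,
                        equilibrium(100), mu=1e-6, n_sample=10, seed=3)
        for c in range(2):
            p = s.positions[s.chrom == c]
            assert np.all(np.diff(p) > 0)

    def test_sample_columns_polymorphic(self):
        s = run_forward([Locus(20_000, 1e-7)], None, equilibrium(150), mu=5e-7,
                        n_sample=4, seed=5)
        counts = s.derived_counts()
        assert counts.min() >= 1 and counts.max() <= s.n_hap - 1

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError, match="cannot sample"):
            run_forward([Locus(1_000, 1e-7)], None, equilibrium(10), mu=1e-7,
                        n_sample=50, seed=1)

    def test_selected_sites_require_dfe(self):
        with pytest.raises(ValueError, match="no DFE"):
            run_forward([Locus(1_000, 1e-7, selected=True)], None,
                        equilibrium(50), mu=1e-7, n_sample=5, seed=1)

    def test_neutral_diversity_matches_4Nmu(self):
        # theta = 4 N mu = 2e-4 per site at N=200, mu=2.5e-7
        pis = []
        for seed in range(12):
            s = run_forward([Locus(40_000, 2.5e-7)], None, equilibrium(200),
                            mu=2.5e-7, n_sample=10, seed=seed)
            pis.append(nucleotide_diversity(s.derived_counts(), s.n_hap) / 40_000)
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - 2e-4) < 3 * se

    def test_bgs_reduces_linked_neutral_diversity(self):
        # a strongly selected exon block flanked by neutral sequence: flank
        # diversity must fall significantly below its analytic neutral
        # expectation 4*N*mu (here by roughly a factor B ~ 0.7)
        sel = np.zeros(60_000, dtype=bool)
        sel[:30_000] = True
        dfe = DiscreteDFE(f=(0.2, 0.0, 0.0, 0.8), Nanc=250)
        vals = []
        for seed in range(10):
            s = run_forward([Locus(60_000, 5e-7, selected=sel)], dfe,
                            equilibrium(250), mu=4e-6, n_sample=10, seed=900 + seed)
            on_flank = s.positions >= 30_000
            vals.append(
                nucleotide_diversity(s.derived_counts()[on_flank], s.n_hap) / 30_000
            )
        pi0 = 4 * 250 * 4e-6
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) < pi0 - 3 * se  # B significantly below 1

    def test_neutral_divergence_matches_molecular_clock(self):
        # post-burn-in fixation rate per neutral site ~ mu per generation
        dem = Demography(epochs=(Epoch(400, 150, 150, "constant"),
                                 Epoch(None, 150, 150, "constant")))
        rates = []
        for seed in range(8):
            s = run_forward([Locus(30_000, 1e-7)], None, dem, mu=1e-6,
                            n_sample=5, seed=seed + 50)
            rates.append(len(s.fixations) / (30_000 * s.generation))
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - 1e-6) < 3 * se + 1e-8

    def test_exonic_divergence_constrained_under_selection(self):
        # strongly deleterious mutations almost never fix: exonic
        # substitution rate falls below the neutral rate mu
        dem = Demography(epochs=(Epoch(400, 200, 200, "constant"),
                                 Epoch(None, 200, 200, "constant")))
        dfe = DiscreteDFE(f=(0.0, 0.0, 0.0, 1.0), Nanc=200)
        tot = 0
        for seed in range(4):
            s = run_forward([Locus(20_000, 1e-7, selected=True)], dfe, dem,
                            mu=1e-6, n_sample=5, seed=seed)
            tot += len(s.fixations)
        expected_neutral = 4 * 20_000 * 400 * 1e-6  # 32 fixations if neutral
        assert tot < 0.25 * expected_neutral

    def test_sample_times_returns_multiple_samples(self):
        dem = Demography(epochs=(Epoch(100, 80, 80, "constant"),
                                 Epoch(None, 120, 120, "constant")))
        out = run_forward([Locus(5_000, 1e-7)], None, dem, mu=1e-6, n_sample=5,
                          seed=2, sample_times=[0, 100])
        assert isinstance(out, list) and len(out) == 2
        assert out[0].generation == 0 and out[1].generation == 100


class TestEngineAgreement:
    def test_forward_and_coalescent_distributions_agree(self):
        # neutral equilibrium: replicate distributions of S and pi from the
        # two engines are indistinguishable (two-sample KS, p > 0.01)
        N, L, n_hap, mu = 200, 20_000, 10, 2.5e-7
        S_f, pi_f = [], []
        for seed in range(80):
            s = run_forward([Locus(L, mu)], None, equilibrium(N), mu=mu,
                            n_sample=n_hap // 2, seed=seed)
            S_f.append(s.n_sites)
            pi_f.append(nucleotide_diversity(s.derived_counts(), n_hap))
        S_c, pi_c = [], []
        for seed in range(80):
            s = run_neutral_coalescent(equilibrium(N), L, n_hap, mu, mu, seed + 1)
            S_c.append(s.n_sites)
            pi_c.append(nucleotide_diversity(s.derived_counts(), n_hap))
        assert sps.ks_2samp(S_f, S_c).pvalue > 0.01
        assert sps.ks_2samp(pi_f, pi_c).pvalue > 0.01


class TestCoalescentEngine:
    def test_zero_mutation_rate(self):
        s = run_neutral_coalescent(equilibrium(1000), 1e5, 10, 0.0, 1e-8, 1)
        assert s.n_sites == 0

    def test_chunking_preserves_total_length_and_mean_S(self):
        whole = segregating_sites_replicates(equilibrium(5000), 4e6, 20, 1e-8,
                                             1e-8, 12, seed=3)
        chunked = segregating_sites_replicates(equilibrium(5000), 4e6, 20, 1e-8,
                                               1e-8, 12, seed=4, chunk_bp=1e6)
        assert sps.ks_2samp(whole, chunked).pvalue > 0.01

    def test_expected_segregating_sites_calibration(self):
        # theta L a_{n-1} at N=5000, mu=1e-8, 1 Mb, 20 haplotypes
        S = segregating_sites_replicates(equilibrium(5000), 1e6, 20, 1e-8, 1e-8,
                                         30, seed=11)
        want = 4 * 5000 * 1e-8 * 1e6 * np.sum(1 / np.arange(1, 20))
        se = S.std(ddof=1) / np.sqrt(30)
        assert abs(S.mean() - want) < 3 * se

    def test_odd_haplotype_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            run_neutral_coalescent(equilibrium(1000), 1e5, 5, 1e-8, 1e-8, 1)

    def test_unlinked_loci_share_sample_dimension(self):
        s = unlinked_loci_sample(equilibrium(2000), 5, 2e4, 20, 1e-7, seed=9)
        assert s.n_hap == 20
        assert len(s.chrom_lengths) == 5


class TestRescalingInvariance:
    def test_diversity_invariant_under_Q(self):
        # matched composite parameters: replicate pi distributions at Q=1
        # and Q=4 are statistically indistinguishable
        from bgsinfer.genomes import equilibrium

        def pis(Q, seeds):
            out = []
            for seed in seeds:
                s = run_forward([Locus(30_000, 2.5e-7)], None, equilibrium(400),
                                mu=2.5e-7, Q=Q, n_sample=10, seed=seed)
                out.append(nucleotide_diversity(s.derived_counts(), s.n_hap))
            return out

        a = pis(1.0, range(40))
        b = pis(4.0, range(100, 140))
        assert sps.ks_2samp(a, b).pvalue > 0.01
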