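import math

import numpy as np
import pytest

from bgsinfer import (
    DiscreteDFE,
    apparent_B_after_change,
    build_genome_layout,
    equilibrium,
    equilibrium_B,
    expected_pi_trajectory,
    expected_segregating_sites,
    expected_sfs_pk,
    exponential_growth,
    instantaneous_decline,
)
from bgsinfer.genomes import Demography, Epoch


def brute_force_B(focal, layout, dfe, u, rec, n_quad=4000):
    """Independent oracle: Monte-Carlo-free Riemann sum over s per exon site."""
    expo = 0.0
    for (lo, hi), f in zip(dfe.bin_bounds, dfe.f):
        if f <= 0:
            continue
        s_grid = np.linspace(lo, hi, n_quad, endpoint=False) + (hi - lo) / (2 * n_quad)
        s_vals = s_grid / (2 * dfe.Nanc)
        t = s_vals / 2
        for es, ee in layout.exon_intervals:
            d = np.abs(np.arange(es, ee) - focal)
            r = 0.5 * (1 - np.exp(-2 * rec * d))
            expo += f * np.mean(
                u * t[None, :] / (t[None, :] + r[:, None] * (1 - t[None, :])) ** 2
            ) * (ee - es)
    return math.exp(-expo)


class TestEquilibriumB:
    def test_matches_brute_force_integration(self):
        lay = build_genome_layout(200, 2, 100, 2000, 2500)
        dfe = DiscreteDFE(f=(0, 0, 0.5, 0.5), Nanc=5000)
        got = equilibrium_B(1200, lay, dfe, mu_del=1e-7, rec_rate=1e-8)
        want = brute_force_B(1200, lay, dfe, 1e-7, 1e-8)
        assert got.B == pytest.approx(want, rel=1e-4)
        assert got.reliable

    def test_distant_site_limit_is_one(self):
        lay = build_genome_layout(200, 2, 100, 10_000_000, 10_000_500)
        dfe = DiscreteDFE(f=(0, 0, 0, 1), Nanc=5000)
        # focal site megabases away: recombination fraction ~ 1/2, B ~ 1
        b = equilibrium_B(9_000_000, lay, dfe, mu_del=1e-8, rec_rate=1e-8)
        assert b.B == pytest.approx(1.0, abs=1e-3)

    def test_tight_linkage_closed_form(self):
        # r = 0: B = exp(-U * E[1/t]) with t = s/2 uniform per bin
        lay = build_genome_layout(100, 1, 1, 1000, 1101)
        dfe = DiscreteDFE(f=(0, 0, 0, 1), Nanc=5000)
        u = 1e-7
        got = equilibrium_B(600, lay, dfe, mu_del=u, rec_rate=0.0)
        lo, hi = 100 / 10_000 / 2, 2 * 5000 / 10_000 / 2  # t bounds of class 3
        e_inv_t = math.log(hi / lo) / (hi - lo)
        assert got.B == pytest.approx(math.exp(-u * 100 * e_inv_t), rel=1e-4)

    def test_B_nondecreasing_with_distance(self):
        lay = build_genome_layout(350, 8, 600, 6300, 13300)
        dfe = DiscreteDFE(f=(0, 0, 0.7, 0.3), Nanc=5000)
        end = lay.gene_intervals[0][1]
        bs = [
            equilibrium_B(end + d, lay, dfe, mu_del=1e-8, rec_rate=1e-8).B
            for d in (10, 100, 1000, 5000)
        ]
        assert all(b1 <= b2 + 1e-12 for b1, b2 in zip(bs, bs[1:]))
        assert all(0 < b <= 1 for b in bs)

    def test_weak_selection_flagged_unreliable(self):
        lay = build_genome_layout(100, 1, 1, 1000, 1101)
        dfe = DiscreteDFE(f=(0.5, 0.5, 0, 0), Nanc=5000)
        with pytest.warns(UserWarning, match="2\\*Nanc\\*s < 10"):
            b = equilibrium_B(600, lay, dfe, mu_del=1e-8, rec_rate=1e-8)
        assert not b.reliable


class TestApparentB:
    def test_limits_return_ancestral_B(self):
        dem = instantaneous_decline()
        assert apparent_B_after_change(0.7, dem, 0.0).B == pytest.approx(0.7)
        assert apparent_B_after_change(0.7, dem, 1e9).B == pytest.approx(0.7, abs=1e-6)

    def test_step_change_closed_form(self):
        # N 10,000 -> 1,667 at t=1,000 with B0=0.8: B-hat ~ 0.755
        dem = Demography(
            epochs=(Epoch(1000, 1667, 1667, "constant"), Epoch(None, 10000, 10000, "constant"))
        )
        assert apparent_B_after_change(0.8, dem, 1000).B == pytest.approx(0.755, abs=0.002)

    def test_direction_decline_below_growth_above(self):
        for t in (50, 200, 500, 1000):
            assert apparent_B_after_change(0.8, instantaneous_decline(), t).B <= 0.8 + 1e-9
            assert apparent_B_after_change(0.8, exponential_growth(), t).B >= 0.8 - 1e-9

    def test_never_exceeds_one(self):
        for t in (0, 100, 1000):
            assert apparent_B_after_change(0.99, exponential_growth(), t).B <= 1 + 1e-9

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            apparent_B_after_change(0.8, instantaneous_decline(), -1.0)


class TestPiTrajectory:
    def test_constant_history_equilibrium_value(self):
        pi = expected_pi_trajectory(equilibrium(5000), 1.0, 1e-8)
        assert pi(0) == pytest.approx(4 * 5000 * 1e-8)
        pi_b = expected_pi_trajectory(equilibrium(5000), 0.5, 1e-8)
        assert pi_b(123) == pytest.approx(4 * 2500 * 1e-8)

    def test_step_change_starts_at_ancestral_value(self):
        dem = instantaneous_decline()
        pi = expected_pi_trajectory(dem, 1.0, 1e-8)
        assert pi(0) == pytest.approx(4 * 12300 * 1e-8)

    def test_continuous_across_epoch_boundary(self):
        dem = exponential_growth()
        pi = expected_pi_trajectory(dem, 1.0, 1e-8)
        vals = [pi(t) for t in np.linspace(0, 1000, 41)]
        diffs = np.abs(np.diff(vals))
        assert np.all(diffs < 0.05 * max(vals))  # no jumps

    def test_matches_coalescent_simulation_mean(self):
        from bgsinfer import run_neutral_coalescent
        from bgsinfer.sumstats import nucleotide_diversity

        dem = exponential_growth(Nanc=2000, Ncur=8000, T=800)
        pis = []
        for seed in range(25):
            s = run_neutral_coalescent(dem, 5e5, 20, 1e-8, 1e-8, seed + 1)
            pis.append(nucleotide_diversity(s.derived_counts(), 20) / 5e5)
        want = expected_pi_trajectory(dem, 1.0, 1e-8)(800)
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - want) < 3 * se


class TestExpectedSfsPK:
    def test_n4_closed_form(self):
        p = expected_sfs_pk(equilibrium(5000), 1.0, 4).p
        assert np.allclose(p, [6 / 11, 3 / 11, 2 / 11])

    def test_constant_history_one_over_b_any_B(self):
        b = np.arange(1, 20)
        want = (1 / b) / (1 / b).sum()
        for B in (1.0, 0.37):
            p = expected_sfs_pk(equilibrium(5000), B, 20).p
            assert np.allclose(p, want, rtol=1e-8)

    def test_B_rescaling_identity_at_one(self):
        dem = instantaneous_decline()
        p1 = expected_sfs_pk(dem, 1.0, 20).p
        p2 = expected_sfs_pk(dem.scaled(1.0), 1.0, 20).p
        assert np.allclose(p1, p2)

    def test_large_samples_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            expected_sfs_pk(equilibrium(5000), 1.0, 80)

    def test_strong_bgs_decline_boosts_singletons(self):
        # strong BGS drives the post-decline spectrum back toward the
        # rare-variant excess of the equilibrated small population
        dem = instantaneous_decline()
        p_neutral = expected_sfs_pk(dem, 1.0, 20).p
        p_bgs = expected_sfs_pk(dem, 0.15, 20).p
        assert p_bgs[0] > p_neutral[0]

    def test_growth_skews_to_singletons(self):
        p_eq = expected_sfs_pk(equilibrium(5000), 1.0, 20).p
        p_gr = expected_sfs_pk(exponential_growth(), 1.0, 20).p
        assert p_gr[0] > p_eq[0]

    def test_expected_segregating_sites_equilibrium(self):
        # theta * L * a_{n-1}
        got = expected_segregating_sites(equilibrium(5000), 1e7, 100, 1e-8)
        a99 = np.sum(1 / np.arange(1, 100))
        assert got == pytest.approx(4 * 5000 * 1e-8 * 1e7 * a99, rel=1e-6)

    def test_matches_coalescent_for_presets(self):
        # relative SFS within 3 SE of simulated proportions for all
        # presets, with and without B rescaling
        from bgsinfer import sfs_counts_replicates

        cases = [
            (equilibrium(5000), 1.0),
            (exponential_growth(), 1.0),
            (instantaneous_decline(), 0.5),
        ]
        for dem, B in cases:
            counts = sfs_counts_replicates(dem.scaled(B), 1.5e6, 20, 1e-8, 1e-8, 25, seed=5)
            props = counts / counts.sum(axis=1, keepdims=True)
            mean = props.mean(axis=0)
            se = props.std(axis=0, ddof=1) / np.sqrt(props.shape[0])
            want = expected_sfs_pk(dem, B, 20).p
            assert np.all(np.abs(mean - want) < 3 * se + 1e-4)
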