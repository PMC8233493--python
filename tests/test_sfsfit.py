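import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgsinfer import (
    MODELS,
    SFS,
    aic,
    akaike_weights,
    composite_loglik,
    equilibrium,
    expected_sfs_model,
    expected_sfs_pk,
    fit_all_models,
    fit_model,
)
from bgsinfer.sfsfit import model_demography
from bgsinfer.theory import ExpectedSFS


def sfs_from_expected(exp, L, rng=None):
    """Turn an expected SFS (with theta) into integer counts over L sites."""
    seg = exp.theta_per_site
    p = np.concatenate([[1 - seg], seg * exp.p])
    if rng is None:
        counts = np.round(p * L).astype(np.int64)
    else:
        counts = rng.multinomial(L, p)
    return SFS(counts=np.concatenate([counts, [0]]), n_hap=exp.n_hap)


class TestExpectedSfsModel:
    def test_equilibrium_is_one_over_b(self):
        p = expected_sfs_model(MODELS["equilibrium"], {"N": 7000}, 20).p
        b = np.arange(1, 20)
        assert np.allclose(p, (1 / b) / (1 / b).sum())

    def test_nested_models_reduce_to_equilibrium(self):
        p_eq = expected_sfs_model(MODELS["equilibrium"], {"N": 5000}, 20).p
        p_inst = expected_sfs_model(
            MODELS["instantaneous_change"], {"Nanc": 5000, "Ncur": 5000, "T": 1000}, 20
        ).p
        assert np.allclose(p_eq, p_inst, atol=1e-10)

    def test_bottleneck_vanishing_intensity(self):
        p_eq = expected_sfs_model(MODELS["equilibrium"], {"N": 5000}, 20).p
        p_bn = expected_sfs_model(
            MODELS["instantaneous_bottleneck"],
            {"Nanc": 5000, "intensity": 1e-5, "T": 1000},
            20,
        ).p
        assert np.allclose(p_eq, p_bn, atol=1e-4)

    def test_bottleneck_pulse_reduces_pair_time_exactly(self):
        # a pulse of intensity I multiplies P(pair survives past T) by e^-I
        from bgsinfer.theory import _discretize, _lambda_integrals

        I, T, N = 0.5, 1000.0, 5000.0
        dem = model_demography(
            MODELS["instantaneous_bottleneck"], {"Nanc": N, "intensity": I, "T": T}
        )
        breaks, sizes = _discretize(dem, 1.0)
        lam2 = _lambda_integrals(breaks, sizes, 2)[0]  # E[T2]
        r = 1 / (2 * N)
        want = (1 - math.exp(-r * T)) / r + math.exp(-r * T) * math.exp(-I) / r
        assert lam2 == pytest.approx(want, rel=1e-6)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            expected_sfs_model(MODELS["equilibrium"], {"N": 10}, 20)


class TestCompositeLoglik:
    def test_hand_computed_value(self):
        obs = SFS(counts=np.array([0, 5, 3, 2, 0]), n_hap=4)
        exp = ExpectedSFS(p=np.array([0.5, 0.3, 0.2]), n_hap=4)
        assert composite_loglik(obs, exp) == pytest.approx(
            5 * math.log(0.5) + 3 * math.log(0.3) + 2 * math.log(0.2)
        )
        assert composite_loglik(obs, exp) == pytest.approx(-10.2965, abs=1e-3)

    def test_gibbs_inequality(self):
        # lnL is maximal when expected proportions equal observed ones
        obs = SFS(counts=np.array([0, 50, 30, 20, 0]), n_hap=4)
        best = composite_loglik(obs, ExpectedSFS(p=np.array([0.5, 0.3, 0.2]), n_hap=4))
        for p in ([0.4, 0.4, 0.2], [0.6, 0.2, 0.2], [1 / 3, 1 / 3, 1 / 3]):
            assert composite_loglik(obs, ExpectedSFS(p=np.array(p), n_hap=4)) < best

    def test_empty_sfs_rejected(self):
        obs = SFS(counts=np.array([100, 0, 0, 0, 0]), n_hap=4)
        exp = ExpectedSFS(p=np.array([0.5, 0.3, 0.2]), n_hap=4)
        with pytest.raises(ValueError):
            composite_loglik(obs, exp)

    def test_monomorphic_class_requires_mu(self):
        obs = SFS(counts=np.array([100, 5, 3, 2, 0]), n_hap=4)
        exp = ExpectedSFS(p=np.array([0.5, 0.3, 0.2]), n_hap=4)  # no theta
        with pytest.raises(ValueError):
            composite_loglik(obs, exp, include_monomorphic=True)


class TestAic:
    def test_formula(self):
        assert aic(3, -100.0) == 206.0
        assert aic(3, -100.0, penalty=25.0) == 275.0
        assert aic(0, -100.0) == 200.0

    def test_weights_two_models(self):
        mc = akaike_weights([100.0, 102.0])
        assert mc.weights[0] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-6)
        assert mc.weights[1] == pytest.approx(0.2689, abs=1e-3)

    def test_weights_equal_and_single(self):
        assert np.allclose(akaike_weights([7.0] * 4).weights, 0.25)
        assert akaike_weights([3.0]).weights[0] == 1.0

    @given(st.lists(st.floats(-500, 500), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_weights_sum_to_one(self, aics):
        assert akaike_weights(aics).weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([1.0, float("nan")])


class TestFitModel:
    def test_equilibrium_self_consistency(self):
        exp = expected_sfs_pk(equilibrium(10_000), 1.0, 20, mu=1e-8)
        obs = sfs_from_expected(exp, 10_000_000)
        fit = fit_model(obs, MODELS["equilibrium"], n_restarts=6, seed=3, mu=1e-8,
                        include_monomorphic=True)
        assert fit.params["N"] == pytest.approx(10_000, rel=0.01)

    def test_nesting_likelihood_ordering(self):
        rng = np.random.default_rng(8)
        exp = expected_sfs_pk(equilibrium(8000), 1.0, 20, mu=1e-8)
        obs = sfs_from_expected(exp, 2_000_000, rng)
        f_eq = fit_model(obs, MODELS["equilibrium"], n_restarts=6, seed=1)
        f_in = fit_model(obs, MODELS["instantaneous_change"], n_restarts=10, seed=2)
        assert f_in.loglik >= f_eq.loglik - 1e-3

    def test_recovers_size_change_parameters(self):
        # median recovery over seeds from multinomial draws of the true model
        from bgsinfer.sfsfit import model_demography

        true = {"Nanc": 9000.0, "Ncur": 2500.0, "T": 1500.0}
        dem = model_demography(MODELS["instantaneous_change"], true)
        exp = expected_sfs_pk(dem, 1.0, 20, mu=1e-8)
        errs = {"Nanc": [], "Ncur": [], "T": []}
        for seed in range(6):
            obs = sfs_from_expected(exp, 5_000_000, np.random.default_rng(seed))
            fit = fit_model(obs, MODELS["instantaneous_change"], n_restarts=12,
                            seed=seed, mu=1e-8, include_monomorphic=True)
            for k in errs:
                errs[k].append(fit.params[k] / true[k] - 1)
        assert abs(np.median(errs["Nanc"])) < 0.10
        assert abs(np.median(errs["Ncur"])) < 0.10
        assert abs(np.median(errs["T"])) < 0.25

    def test_deterministic_given_seed(self):
        exp = expected_sfs_pk(equilibrium(5000), 1.0, 10, mu=1e-8)
        obs = sfs_from_expected(exp, 500_000)
        f1 = fit_model(obs, MODELS["exponential_change"], n_restarts=4, seed=9)
        f2 = fit_model(obs, MODELS["exponential_change"], n_restarts=4, seed=9)
        assert f1.params == f2.params and f1.loglik == f2.loglik

    def test_strict_penalty_favors_equilibrium(self):
        # near-equilibrium data: the 25x penalty should pick the
        # one-parameter model at least as often as the standard penalty
        rng = np.random.default_rng(4)
        exp = expected_sfs_pk(equilibrium(6000), 1.0, 20, mu=1e-8)
        chosen = {2.0: 0, 25.0: 0}
        for seed in range(4):
            obs = sfs_from_expected(exp, 300_000, rng)
            for pen in (2.0, 25.0):
                _, choice = fit_all_models(obs, n_restarts=5, seed=seed, mu=1e-8,
                                           include_monomorphic=True, penalty=pen)
                chosen[pen] += choice.selected == "equilibrium"
        assert chosen[25.0] >= chosen[2.0]
        assert chosen[25.0] >= 3

    def test_fit_result_aic_consistency(self):
        exp = expected_sfs_pk(equilibrium(5000), 1.0, 10, mu=1e-8)
        obs = sfs_from_expected(exp, 500_000)
        fit = fit_model(obs, MODELS["equilibrium"], n_restarts=3, seed=0)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.aic25 == pytest.approx(25 * fit.k - 2 * fit.loglik)
        assert fit.L10 == pytest.approx(fit.loglik / math.log(10))
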