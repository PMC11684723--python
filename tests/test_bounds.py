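"""Renyi / chi evidence bounds and the combined point-process surrogate."""

import numpy as np
import pytest
from scipy.special import logsumexp

from mppvae import autodiff as ad
from mppvae.bounds import (BoundConfig, bin_loglik_lower_bound, chi_term_value,
                           chi_upper_bound, jackknife_correct,
                           pp_loglik_lower_bound, renyi_lower_bound, spike_term)
from mppvae.linear_gaussian import make_linear_gaussian_jmi, sample_log_weights


class TestRenyi:
    def test_constant_weights_return_the_constant(self):
        lw = np.full(6, np.log(2.0))
        for alpha in (0.1, 0.5, 1.0):
            assert renyi_lower_bound(lw, alpha) == pytest.approx(np.log(2.0))

    def test_alpha_one_is_log_mean_weight(self):
        lw = np.array([0.0, np.log(3.0)])
        assert renyi_lower_bound(lw, 1.0) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_monotone_in_alpha_and_matches_direct_evaluation(self):
        lw = np.array([0.0, np.log(3.0)])
        vals = []
        for alpha in (0.3, 0.9, 1.0):
            direct = np.log(np.mean(np.exp(lw) ** alpha)) / alpha
            got = renyi_lower_bound(lw, alpha)
            assert got == pytest.approx(direct, abs=1e-12)
            vals.append(got)
        assert vals[0] <= vals[1] <= vals[2]

    def test_alpha_near_zero_recovers_the_elbo_limit(self, rng):
        lw = rng.standard_normal(200)
        assert renyi_lower_bound(lw, 1e-4) == pytest.approx(lw.mean(), abs=1e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            renyi_lower_bound(np.zeros(3), 0.0)
        with pytest.raises(ValueError):
            renyi_lower_bound(np.zeros(3), 1.5)

    def test_all_zero_weights_give_neg_inf(self):
        assert renyi_lower_bound(np.full(4, -np.inf), 0.5) == -np.inf

    def test_no_overflow_for_extreme_log_weights(self):
        lw = np.array([-700.0, 700.0])
        assert np.isfinite(renyi_lower_bound(lw, 0.5))
        assert np.isfinite(chi_upper_bound(lw, 2.0))


class TestChi:
    def test_constant_weights(self):
        lw = np.full(5, np.log(3.0))
        assert chi_upper_bound(lw, 2.0) == pytest.approx(np.log(3.0))

    def test_beta_two_power_mean(self):
        lw = np.log(np.array([1.0, 3.0]))
        assert chi_upper_bound(lw, 2.0) == pytest.approx(np.log(np.sqrt(5.0)), abs=1e-12)

    def test_power_mean_dominates_arithmetic_mean(self, rng):
        w = rng.lognormal(size=(50, 8))
        pm = np.exp(chi_upper_bound(np.log(w), 2.0))
        am = w.mean(axis=-1)
        direct = np.sqrt((w ** 2).mean(axis=-1))
        np.testing.assert_allclose(pm, direct, rtol=1e-12)
        assert np.all(pm >= am - 1e-12)

    def test_beta_validation(self):
        with pytest.raises(ValueError):
            chi_upper_bound(np.zeros(3), 1.0)

    def test_all_zero_weights_give_zero_chi_term(self):
        assert chi_term_value(np.full(3, -np.inf), 2.0) == 0.0


class TestSpikeTerm:
    def test_zero_scale_is_identity(self, rng):
        lw = rng.standard_normal(10)
        assert spike_term(lw, 0.7, 0.0) == pytest.approx(renyi_lower_bound(lw, 0.7))

    def test_scale_additivity(self, rng):
        lw = rng.standard_normal(16)
        for alpha in (0.2, 1.0):
            diff = spike_term(lw, alpha, 1.37) - renyi_lower_bound(lw, alpha)
            assert diff == pytest.approx(1.37, abs=1e-12)

    def test_constant_weights_add_scales(self):
        lw = np.full(4, np.log(5.0))
        assert spike_term(lw, 0.5, np.log(2.0)) == pytest.approx(np.log(10.0))


class TestBinAndDatasetBounds:
    def test_empty_bin_reduces_to_negative_chi_term(self):
        cfg = BoundConfig(use_jackknife=False)
        state = np.full(cfg.L, np.log(3.0))
        out = bin_loglik_lower_bound([], state, cfg, np.log(2.0))
        assert out == pytest.approx(-2.0 * 3.0)

    def test_single_sample_collapse(self):
        cfg = BoundConfig(L=1, use_jackknife=False)
        lam0 = 1.7
        out = bin_loglik_lower_bound([np.array([0.3])], np.array([np.log(0.5)]),
                                     cfg, np.log(lam0))
        assert out == pytest.approx(np.log(lam0) + 0.3 - lam0 * 0.5)

    def test_no_spike_dataset_limit(self):
        cfg = BoundConfig(use_jackknife=False)
        states = [np.full(cfg.L, np.log(0.4))] * 7
        out = pp_loglik_lower_bound([], states, cfg, np.log(2.0))
        assert out == pytest.approx(-7 * 2.0 * 0.4)

    def test_degenerate_latent_equals_exact_loglik(self, rng):
        # constant densities: w_l identical for all l -> bound is exact for
        # any L, alpha, beta
        cfg = BoundConfig(alpha=0.37, beta=3.0, L=5, use_jackknife=False)
        d_spike, d_state = 0.8, 0.25
        lam0 = 2.0
        spikes = [np.full(cfg.L, np.log(d_spike))] * 3
        states = [np.full(cfg.L, np.log(d_state))] * 10
        out = pp_loglik_lower_bound(spikes, states, cfg, np.log(lam0))
        exact = 3 * np.log(lam0 * d_spike) - 10 * lam0 * d_state
        assert out == pytest.approx(exact, rel=1e-12)

    def test_bound_below_exact_on_tractable_model(self, lg_jmi, lg_point):
        x, k = lg_point
        lg = make_linear_gaussian_jmi(seed=7, variance_inflation=2.0)
        lw = sample_log_weights(lg, x, k, L=10, n_rep=400, seed=0)
        mean_renyi = np.mean([renyi_lower_bound(lw[i], 0.5) for i in range(400)])
        assert mean_renyi <= lg.log_evidence_xk(x, k) + 1e-9


class TestJackknife:
    def test_linear_statistic_unchanged(self, rng):
        s = rng.standard_normal(12)
        out = jackknife_correct(lambda sub: float(np.mean(sub)), s)
        assert out == pytest.approx(s.mean(), abs=1e-12)

    def test_L2_formula_instantiation(self):
        s = np.array([1.0, 5.0])
        est = lambda sub: float(np.max(sub))
        expected = 2 * 5.0 - (1.0 + 5.0) / 2
        assert jackknife_correct(est, s) == pytest.approx(expected)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            jackknife_correct(lambda s: 0.0, np.zeros(1))

    def test_reduces_bias_of_log_mean_weight(self, lg_jmi, lg_point):
        # log-mean-weight estimator of a known log evidence at L=8
        x, k = lg_point
        lg = make_linear_gaussian_jmi(seed=7, variance_inflation=3.0)
        truth = lg.log_evidence_xk(x, k)
        lw = sample_log_weights(lg, x, k, L=8, n_rep=4000, seed=1)
        plain = logsumexp(lw, axis=-1) - np.log(8)
        corrected = np.array([jackknife_correct(
            lambda sub: float(logsumexp(sub) - np.log(sub.shape[-1])), lw[i])
            for i in range(1000)])
        bias_plain = abs(plain[:1000].mean() - truth)
        bias_corr = abs(corrected.mean() - truth)
        assert bias_corr < bias_plain


class TestDReG:
    def test_dreg_gradient_matches_finite_difference(self):
        # alpha = 1 objective on the tractable model: the sample-mean DReG
        # encoder gradient must agree with a central finite difference of
        # the exact bound within Monte-Carlo error
        from mppvae.jmi_vae import mc_bound
        lg = make_linear_gaussian_jmi(seed=3, variance_inflation=2.0)
        model = lg.model
        model.bound_cfg = BoundConfig(alpha=1.0, beta=2.0, L=8,
                                      use_jackknife=False, use_dreg=True)
        rng = np.random.default_rng(0)
        xs = rng.standard_normal((4, 2))
        ks = rng.standard_normal((4, 3))
        xg = rng.standard_normal((6, 2))
        p = model.encoder_xk.b_mean
        n_rep = 300
        grads, vals_p, vals_m = [], [], []
        eps_fd = 1e-4
        for i in range(n_rep):
            rr = np.random.default_rng(100 + i)
            eps_pair = (rr.standard_normal((4, 8, 1)), rr.standard_normal((6, 8, 1)))
            bound, surrogate = mc_bound(model, xs, ks, xg, model.bound_cfg,
                                        eps_pair=eps_pair, dreg=True)
            for q in model.parameters():
                q.grad = None
            surrogate.backward()
            grads.append(p.grad[0].copy())
            orig = p.value.copy()
            p.value = orig + np.array([eps_fd])
            vals_p.append(float(ad.value_of(mc_bound(model, xs, ks, xg, model.bound_cfg,
                                                     eps_pair=eps_pair))))
            p.value = orig - np.array([eps_fd])
            vals_m.append(float(ad.value_of(mc_bound(model, xs, ks, xg, model.bound_cfg,
                                                     eps_pair=eps_pair))))
            p.value = orig
        g_dreg = np.mean(grads)
        g_fd = (np.mean(vals_p) - np.mean(vals_m)) / (2 * eps_fd)
        se = np.std(grads) / np.sqrt(n_rep) + 1e-6
        fd_se = np.std((np.array(vals_p) - np.array(vals_m)) / (2 * eps_fd)) / np.sqrt(n_rep)
        assert abs(g_dreg - g_fd) < 3 * (se + fd_se)


def test_bound_config_validation_and_round_trip():
    with pytest.raises(ValueError):
        BoundConfig(alpha=0.0)
    with pytest.raises(ValueError):
        BoundConfig(beta=1.0)
    with pytest.raises(ValueError):
        BoundConfig(L=0)
    cfg = BoundConfig(alpha=0.3, beta=4.0, L=7)
    assert BoundConfig.from_dict(cfg.to_dict()) == cfg
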