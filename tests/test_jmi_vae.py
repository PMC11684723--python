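"""Joint mark intensity VAE: construction, estimates, observed-state fit."""

import numpy as np
import pytest

from mppvae import autodiff as ad
from mppvae.bounds import BoundConfig
from mppvae.jmi_vae import (JointMarkIntensityVAE, TrainConfig, build_model,
                            fit_observed_state, ground_intensity_estimate,
                            intensity_estimate, mc_bound, nll_bound)
from mppvae.linear_gaussian import make_linear_gaussian_jmi
from mppvae.nets import make_affine_gaussian_net


class TestBuild:
    def test_same_seed_same_parameters(self):
        m1 = build_model(3, 4, 2, seed=11)
        m2 = build_model(3, 4, 2, seed=11)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_shape_contract(self):
        m = build_model(d_x=3, d_k=4, d_z=2, seed=0)
        mean_x, _ = m.decoder_x.forward_np(np.zeros((5, 2)))
        mean_k, _ = m.decoder_k.forward_np(np.zeros((5, 2)))
        assert mean_x.shape == (5, 3) and mean_k.shape == (5, 4)

    def test_precisions_positive_for_random_inputs(self, rng):
        m = build_model(3, 4, 2, seed=0)
        for net, din in ((m.decoder_x, 2), (m.encoder_xk, 7), (m.encoder_x, 3)):
            _, prec = net.forward_np(rng.standard_normal((100, din)) * 3)
            assert np.all(prec > 0)       # diagonal SPD by construction

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            build_model(0, 1, 1)

    def test_checkpoint_round_trip(self, tmp_path):
        m = build_model(3, 4, 2, seed=5)
        path = str(tmp_path / "ckpt.npz")
        m.save(path)
        m2 = JointMarkIntensityVAE.load(path)
        for p1, p2 in zip(m.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1.value, p2.value)
        assert m2.bound_cfg == m.bound_cfg


class TestConditionalIndependence:
    def test_joint_decoder_density_factorizes(self, rng):
        m = build_model(3, 4, 2, seed=1)
        z = ad.Tensor(rng.standard_normal((10, 2)))
        x = rng.standard_normal((10, 3))
        k = rng.standard_normal((10, 4))
        joint = ad.value_of(m.log_p_xk_given_z(x, k, z))
        parts = ad.value_of(m.log_p_x_given_z(x, z)) + ad.value_of(m.log_p_k_given_z(k, z))
        np.testing.assert_allclose(joint, parts, atol=1e-12)


class TestIntensityEstimates:
    def test_degenerate_latent_gives_lambda0_times_density(self):
        # decoders that ignore z: estimate = lambda0 * density exactly, any S
        m = build_model(1, 1, 1, seed=0, lambda0_init=3.0)
        m.decoder_x = make_affine_gaussian_net(np.zeros((1, 1)), [0.0], [2 * np.pi])
        m.decoder_k = make_affine_gaussian_net(np.zeros((1, 1)), [0.0], [2 * np.pi])
        # with a z-independent decoder the exact posterior is the prior
        m.encoder_xk = make_affine_gaussian_net(np.zeros((2, 1)), [0.0], [1.0])
        # peak density of N(0, (2pi)^-1) at 0 is 1 for each factor
        for S in (1, 7):
            assert intensity_estimate(m, [0.0], [0.0], S=S, seed=3) == pytest.approx(3.0, rel=1e-9)

    def test_vanishing_scale(self):
        m = build_model(2, 2, 1, seed=0)
        m.log_lambda0.value = np.array(-50.0)
        assert intensity_estimate(m, [0.0, 0.0], [0.0, 0.0], S=4, seed=0) <= 1e-20

    def test_linear_gaussian_closed_form(self, rng):
        lg = make_linear_gaussian_jmi(d_x=2, d_k=3, d_z=1, lambda0=2.0, seed=7)
        x, k = rng.standard_normal(2), rng.standard_normal(3)
        truth = 2.0 * np.exp(lg.log_evidence_xk(x, k))
        # exact-posterior proposal: exact at any S
        assert intensity_estimate(lg.model, x, k, S=1, seed=0) == pytest.approx(truth, rel=1e-9)
        # prior-sampling oracle: consistent within 3 relative SE at S = 1e4
        est = intensity_estimate(lg.model, x, k, S=10_000, seed=1, proposal="prior")
        assert est == pytest.approx(truth, rel=0.1)

    def test_ground_intensity_marginalization_consistency(self, rng):
        lg = make_linear_gaussian_jmi(seed=9)
        x = rng.standard_normal(2)
        truth = 1.0 * lg.evidence_x(x)
        assert ground_intensity_estimate(lg.model, x, S=1, seed=0) == pytest.approx(truth, rel=1e-9)

    def test_linearity_in_lambda0_at_fixed_seed(self, rng):
        m = build_model(2, 3, 2, seed=2)
        x, k = rng.standard_normal(2), rng.standard_normal(3)
        v1 = intensity_estimate(m, x, k, S=64, seed=5)
        m.log_lambda0.value = m.log_lambda0.value + np.log(2.0)
        v2 = intensity_estimate(m, x, k, S=64, seed=5)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)
        assert v1 >= 0

    def test_nonfinite_inputs_rejected(self):
        m = build_model(2, 2, 1, seed=0)
        with pytest.raises(ValueError):
            intensity_estimate(m, [np.nan, 0.0], [0.0, 0.0], S=2)


class TestFitObservedState:
    def test_zero_epochs_is_a_no_op(self, rng):
        m = build_model(2, 3, 2, seed=0)
        before = [p.value.copy() for p in m.parameters()]
        fit_observed_state(m, rng.standard_normal((5, 2)), rng.standard_normal((5, 3)),
                           rng.standard_normal((20, 2)),
                           TrainConfig(epochs=0, init_lambda0_from_rate=False))
        for p, b in zip(m.parameters(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_training_improves_held_out_bound(self, rng):
        # data from a 1-component linear-Gaussian generator
        lg = make_linear_gaussian_jmi(d_x=2, d_k=3, d_z=1, seed=4)
        z = rng.standard_normal((500, 1))
        xs = z @ lg.A_x + lg.c_x + rng.standard_normal((500, 2)) / np.sqrt(lg.prec_x)
        ks = z @ lg.A_k + lg.c_k + rng.standard_normal((500, 3)) / np.sqrt(lg.prec_k)
        xg = rng.standard_normal((300, 2))
        val = (xs[400:], ks[400:], xg[250:])
        model = build_model(2, 3, 2, hidden=(16,), seed=0,
                            bound_cfg=BoundConfig(L=5, use_jackknife=False))
        before = float(ad.value_of(mc_bound(model, *val, model.bound_cfg,
                                            rng=np.random.default_rng(0))))
        model, trace = fit_observed_state(
            model, xs[:400], ks[:400], xg[:250],
            TrainConfig(epochs=60, lr=3e-3, seed=0), val_data=val)
        after = float(ad.value_of(mc_bound(model, *val, model.bound_cfg,
                                           rng=np.random.default_rng(0))))
        assert after > before

    def test_homogeneous_rate_recovery(self, rng):
        # constant decoders with unit peak density: lambda0 MLE = n / (m dt)
        m = build_model(1, 1, 1, seed=0, bound_cfg=BoundConfig(L=4, use_jackknife=False))
        m.decoder_x = make_affine_gaussian_net(np.zeros((1, 1)), [0.0], [2 * np.pi])
        m.decoder_k = make_affine_gaussian_net(np.zeros((1, 1)), [0.0], [2 * np.pi])
        n, mgrid, dt = 120, 400, 0.05
        xs = np.zeros((n, 1))
        ks = np.zeros((n, 1))
        xg = np.zeros((mgrid, 1))
        m, _ = fit_observed_state(m, xs, ks, xg,
                                  TrainConfig(epochs=200, lr=0.02, dt=dt, seed=0,
                                              patience=50, val_fraction=0.1))
        target = n * 0.9 / (mgrid * 0.9 * dt)   # training split of both
        assert m.lambda0 == pytest.approx(target, rel=0.1)


class TestNllBound:
    def test_matches_negative_bound_by_construction(self, rng):
        lg = make_linear_gaussian_jmi(seed=3)
        xs, ks = rng.standard_normal((4, 2)), rng.standard_normal((4, 3))
        xg = rng.standard_normal((9, 2))
        nll = nll_bound(lg.model, xs, ks, xg, seed=2)
        b = float(ad.value_of(mc_bound(lg.model, xs, ks, xg, lg.model.bound_cfg,
                                       rng=np.random.default_rng(2))))
        assert nll == pytest.approx(-b)

    def test_no_spike_data_gives_positive_nll(self, rng):
        lg = make_linear_gaussian_jmi(seed=3)
        xg = rng.standard_normal((9, 2))
        assert nll_bound(lg.model, np.zeros((0, 2)), np.zeros((0, 3)), xg, seed=0) > 0

    def test_upper_bounds_exact_nll_on_tractable_model(self, rng):
        lg = make_linear_gaussian_jmi(seed=5, variance_inflation=2.5)
        xs, ks = rng.standard_normal((6, 2)), rng.standard_normal((6, 3))
        xg = rng.standard_normal((12, 2))
        exact_ll = sum(lg.log_evidence_xk(x, k) for x, k in zip(xs, ks)) \
            - sum(lg.evidence_x(x) for x in xg)   # lambda0 = 1
        nlls = [nll_bound(lg.model, xs, ks, xg, seed=s) for s in range(40)]
        assert np.mean(nlls) >= -exact_ll - 1e-6
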