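"""State-space model: structured posterior assembly, ELBO, training."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mppvae import autodiff as ad
from mppvae import state_space as ss
from mppvae.core_data import BinnedDataset
from mppvae.jmi_vae import build_model
from mppvae.nets import make_affine_gaussian_net


def _empty_bins(R, d_k=3):
    return [np.zeros((0, d_k))] * R


def _flat_base(q, d):
    q.base_logprec.value = np.full(d, -30.0)   # ~zero-precision base expert
    q.base_mean.value = np.zeros(d)


def _linear_setup(rng, d=2, D_y=2, R=6):
    """Fully linear-Gaussian no-spike model + matching exact posterior."""
    jmi = build_model(d, 3, 2, hidden=(8,), seed=0)
    model = ss.StateSpaceModel(d, D_y, jmi, hidden=(8,), seed=1)
    F = 0.9 * np.eye(d)
    a = np.array([0.1, -0.2])
    V = 2.0 * np.eye(d)
    V1 = np.eye(d)
    a1 = np.zeros(d)
    model.dyn = ss.LinearGaussianDynamics.from_matrices(a1, V1, F, a, V)
    C = np.diag([1.5, 0.7])
    c0 = np.array([0.2, -0.1])
    Lam = np.array([3.0, 1.0])
    model.obs_y = make_affine_gaussian_net(C.T, c0, Lam)
    y = rng.standard_normal((R, D_y))
    data = BinnedDataset(0.01, R, y, _empty_bins(R))
    q = ss.StructuredVariationalFamily(d, D_y, 3, hidden=(8,), seed=5)
    q.qdyn = ss.LinearGaussianDynamics.from_matrices(a1, V1, F, a, V)
    ep = np.diag(C.T @ np.diag(Lam) @ C)
    Wy = np.linalg.inv(np.diag(ep)) @ C.T @ np.diag(Lam)
    q.enc_y = make_affine_gaussian_net(Wy.T, -Wy @ c0, ep)
    _flat_base(q, d)
    return model, q, data, (a1, V1, F, a, V, C, c0, Lam, y)


def _dense_logmarg(parts, R, d):
    a1, V1, F, a, V, C, c0, Lam, y = parts
    Pp = np.zeros((R * d, R * d))
    hp = np.zeros(R * d)
    Pp[:d, :d] += V1
    hp[:d] += V1 @ a1
    for r in range(R - 1):
        i, j = r * d, (r + 1) * d
        Pp[j:j + d, j:j + d] += V
        Pp[i:i + d, i:i + d] += F.T @ V @ F
        Pp[i:i + d, j:j + d] += -F.T @ V
        Pp[j:j + d, i:i + d] += -V @ F
        hp[j:j + d] += V @ a
        hp[i:i + d] += -F.T @ V @ a
    Sx = np.linalg.inv(Pp)
    mux = Sx @ hp
    Cb = np.kron(np.eye(R), C)
    my = Cb @ mux + np.tile(c0, R)
    Sy = Cb @ Sx @ Cb.T + np.kron(np.eye(R), np.diag(1.0 / Lam))
    return multivariate_normal(mean=my, cov=Sy).logpdf(y.reshape(-1))


class TestStructuredPosterior:
    def test_single_standard_factor(self):
        d = 2
        q = ss.StructuredVariationalFamily(d, 1, 1, hidden=(4,), seed=0)
        q.qdyn = ss.LinearGaussianDynamics.from_matrices(
            np.zeros(d), np.eye(d), np.eye(d), np.zeros(d), np.eye(d))
        _flat_base(q, d)
        data = BinnedDataset(0.01, 1, np.zeros((1, 1)), [np.zeros((0, 1))])
        post, _ = ss.build_structured_posterior(q, data, include_y=False)
        np.testing.assert_allclose(ad.value_of(post.mean), 0.0, atol=1e-9)
        np.testing.assert_allclose(post.precision.to_dense(), np.eye(d), atol=1e-5)

    def test_two_scalar_experts_multiply(self):
        # N(.|0, prec 1) x N(.|2, prec 1) -> mean 1, precision 2
        d = 1
        q = ss.StructuredVariationalFamily(d, 1, 1, hidden=(4,), seed=0)
        q.qdyn = ss.LinearGaussianDynamics.from_matrices(
            np.zeros(d), np.eye(d), np.eye(d), np.zeros(d), np.eye(d))
        _flat_base(q, d)
        q.enc_y = make_affine_gaussian_net(np.zeros((1, 1)), [2.0], [1.0])
        data = BinnedDataset(0.01, 1, np.zeros((1, 1)), [np.zeros((0, 1))])
        post, _ = ss.build_structured_posterior(q, data)
        assert ad.value_of(post.mean)[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert post.precision.to_dense()[0, 0] == pytest.approx(2.0, abs=1e-5)

    def test_matches_dense_information_filter(self, rng):
        for trial in range(5):
            d, D_y, D_k, R = 3, 2, 4, 4
            q = ss.StructuredVariationalFamily(d, D_y, D_k, hidden=(8,), seed=trial)
            q.qdyn.F.value = 0.3 * rng.standard_normal((d, d))
            q.qdyn.a.value = rng.standard_normal(d) * 0.5
            q.qdyn.a1.value = rng.standard_normal(d)
            B = rng.standard_normal((d, d))
            q.qdyn.V1p = ss.SPDParam(d, B @ B.T + np.eye(d))
            y = rng.standard_normal((R, D_y))
            data = BinnedDataset(0.01, R, y,
                                 [rng.standard_normal((n, D_k))
                                  for n in rng.integers(0, 4, R)])
            post, _ = ss.build_structured_posterior(q, data)
            # dense product-of-Gaussians oracle
            W1 = ad.value_of(q.qdyn.V1p.matrix())
            W = ad.value_of(q.qdyn.Vp.matrix())
            G, b1, b = q.qdyn.F.value, q.qdyn.a1.value, q.qdyn.a.value
            P = np.zeros((R * d, R * d))
            h = np.zeros(R * d)
            P[:d, :d] += W1
            h[:d] += W1 @ b1
            for r in range(R - 1):
                i, j = r * d, (r + 1) * d
                P[j:j + d, j:j + d] += W
                P[i:i + d, i:i + d] += G.T @ W @ G
                P[i:i + d, j:j + d] += -G.T @ W
                P[j:j + d, i:i + d] += -W @ G
                h[j:j + d] += W @ b
                h[i:i + d] += -G.T @ W @ b
            bm, bp = (ad.value_of(v) for v in q.base_expert())
            for r in range(R):
                ym, yp = q.enc_y.forward_np(y[r])
                P[r * d:(r + 1) * d, r * d:(r + 1) * d] += np.diag(yp + bp)
                h[r * d:(r + 1) * d] += yp * ym + bp * bm
                for mk in data.mark_sets[r]:
                    km, kp = q.enc_k.forward_np(mk)
                    P[r * d:(r + 1) * d, r * d:(r + 1) * d] += np.diag(kp)
                    h[r * d:(r + 1) * d] += kp * km
            np.testing.assert_allclose(post.precision.to_dense(), P, rtol=1e-8, atol=1e-8)
            np.testing.assert_allclose(ad.value_of(post.mean),
                                       np.linalg.solve(P, h).reshape(R, d),
                                       rtol=1e-6, atol=1e-8)


class TestElbo:
    def test_exact_posterior_recovers_log_marginal(self, rng):
        model, q, data, parts = _linear_setup(rng)
        truth = _dense_logmarg(parts, data.R, 2)
        e = float(ad.value_of(ss.elbo(model, q, data, n_mc=3, seed=7,
                                      include_spike_terms=False)))
        assert e == pytest.approx(truth, abs=1e-4)

    def test_perturbed_posterior_is_worse(self, rng):
        model, q, data, parts = _linear_setup(rng)
        e_exact = float(ad.value_of(ss.elbo(model, q, data, n_mc=256, seed=3,
                                            include_spike_terms=False)))
        q.qdyn.a.value = q.qdyn.a.value + 0.5
        e_pert = float(ad.value_of(ss.elbo(model, q, data, n_mc=256, seed=3,
                                           include_spike_terms=False)))
        assert e_exact >= e_pert

    def test_elbo_below_exact_evidence(self, rng):
        model, q, data, parts = _linear_setup(rng)
        truth = _dense_logmarg(parts, data.R, 2)
        q.qdyn.a.value = q.qdyn.a.value + 0.3   # suboptimal posterior
        vals = [float(ad.value_of(ss.elbo(model, q, data, n_mc=8, seed=s,
                                          include_spike_terms=False)))
                for s in range(20)]
        assert np.mean(vals) <= truth + 3 * np.std(vals) / np.sqrt(20)

    def test_mc_consistency_when_doubling_samples(self, rng):
        model, q, data, _ = _linear_setup(rng)
        q.qdyn.b = None  # not used; q remains exact -> zero-variance integrand
        e1 = float(ad.value_of(ss.elbo(model, q, data, n_mc=4, seed=1,
                                       include_spike_terms=False)))
        e2 = float(ad.value_of(ss.elbo(model, q, data, n_mc=8, seed=1,
                                       include_spike_terms=False)))
        assert e1 == pytest.approx(e2, abs=1e-6)

    def test_invalid_n_mc(self, rng):
        model, q, data, _ = _linear_setup(rng)
        with pytest.raises(ValueError):
            ss.elbo(model, q, data, n_mc=0)


class TestFitPredict:
    def test_zero_epochs_identity(self, rng):
        model, q, data, _ = _linear_setup(rng)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        ss.fit(model, q, data, ss.SSMTrainConfig(epochs=0))
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_linear_truth_initialization_is_stable(self, rng):
        model, q, data, parts = _linear_setup(rng, R=12)
        truth = _dense_logmarg(parts, data.R, 2)
        cfg = ss.SSMTrainConfig(epochs=10, lr=1e-4, n_mc=2, val_n_mc=8,
                                init_lambda0_from_rate=False, patience=100)
        model, q, trace = ss.fit(model, q, data, cfg, val_data=data)
        # validation ELBO stays within MC noise of the exact evidence
        assert max(trace["val"]) <= truth + 1.0
        assert trace["val"][-1] > truth - 5.0

    def test_predict_nll_is_negative_elbo(self, rng):
        model, q, data, _ = _linear_setup(rng)
        nll = ss.predict_nll(model, q, data, n_mc=4, seed=9, include_spike_terms=False)
        e = float(ad.value_of(ss.elbo(model, q, data, n_mc=4, seed=9,
                                      include_spike_terms=False)))
        assert nll == pytest.approx(-e)

    def test_corrupting_observation_model_raises_nll(self, rng):
        model, q, data, _ = _linear_setup(rng)
        base = ss.predict_nll(model, q, data, n_mc=16, seed=2, include_spike_terms=False)
        model.obs_y.b_mean.value = model.obs_y.b_mean.value + 5.0
        worse = ss.predict_nll(model, q, data, n_mc=16, seed=2, include_spike_terms=False)
        assert worse > base
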