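"""Tractable linear-Gaussian instance of the joint mark intensity model.

With affine decoders x = A_x' z + c_x + noise, kappa = A_k' z + c_k +
noise and a standard-normal latent, the evidences p(x, kappa) and p(x)
are Gaussian in closed form and the exact latent posteriors are
conjugate Gaussians.  This instance is the workhorse oracle for the
bound sandwich, tightness, jackknife-debiasing and estimator checks: the
bounds can be compared against exact evidences, and the encoders can be
set to the exact posteriors (or variance-inflated versions of them,
which re-introduces Monte-Carlo gap and bias in a controlled way).

Restriction: the latent is one-dimensional (or the loading columns are
orthogonal) so the exact posterior precision is diagonal and
representable by the diagonal-precision Gaussian networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal

from .jmi_vae import JointMarkIntensityVAE, build_model
from .nets import make_affine_gaussian_net


@dataclass
class LinearGaussianJMI:
    """Model + closed forms for the affine special case."""

    model: JointMarkIntensityVAE
    A_x: np.ndarray      # (d_z, d_x)
    c_x: np.ndarray
    prec_x: np.ndarray   # diagonal noise precision
    A_k: np.ndarray
    c_k: np.ndarray
    prec_k: np.ndarray

    # -- closed forms ---------------------------------------------------
    def joint_cov(self):
        B = np.concatenate([self.A_x, self.A_k], axis=1)
        noise = np.concatenate([1.0 / self.prec_x, 1.0 / self.prec_k])
        return B.T @ B + np.diag(noise)

    def log_evidence_xk(self, x, k):
        """log p(x, kappa) (without lambda0)."""
        u = np.concatenate([np.atleast_1d(x), np.atleast_1d(k)])
        c = np.concatenate([self.c_x, self.c_k])
        return float(multivariate_normal(mean=c, cov=self.joint_cov()).logpdf(u))

    def evidence_x(self, x):
        """p(x) (without lambda0)."""
        cov = self.A_x.T @ self.A_x + np.diag(1.0 / self.prec_x)
        return float(multivariate_normal(mean=self.c_x, cov=cov).pdf(np.atleast_1d(x)))

    def posterior_xk(self, x, k):
        """Exact N(z | m, P^-1) given (x, kappa); P is (d_z, d_z)."""
        B = np.concatenate([self.A_x, self.A_k], axis=1)
        Pu = np.concatenate([self.prec_x, self.prec_k])
        c = np.concatenate([self.c_x, self.c_k])
        P = np.eye(B.shape[0]) + (B * Pu) @ B.T
        u = np.concatenate([np.atleast_1d(x), np.atleast_1d(k)])
        m = np.linalg.solve(P, (B * Pu) @ (u - c))
        return m, P

    def posterior_x(self, x):
        Pu = self.prec_x
        P = np.eye(self.A_x.shape[0]) + (self.A_x * Pu) @ self.A_x.T
        m = np.linalg.solve(P, (self.A_x * Pu) @ (np.atleast_1d(x) - self.c_x))
        return m, P

    # -- encoder control -------------------------------------------------
    def set_exact_encoders(self, variance_inflation=1.0):
        """Install the exact-posterior encoders, optionally with their
        variance inflated (precision divided) by `variance_inflation`;
        inflation > 1 reopens the Monte-Carlo gap in a controlled way."""
        B = np.concatenate([self.A_x, self.A_k], axis=1)
        Pu = np.concatenate([self.prec_x, self.prec_k])
        c = np.concatenate([self.c_x, self.c_k])
        P = np.eye(B.shape[0]) + (B * Pu) @ B.T
        if not np.allclose(P, np.diag(np.diag(P)), atol=1e-10):
            raise ValueError("posterior precision not diagonal; use orthogonal loadings")
        W = np.linalg.solve(P, (B * Pu)).T            # (d_u, d_z)
        self.model.encoder_xk = make_affine_gaussian_net(
            W, -c @ W, np.diag(P) / variance_inflation)
        Px = np.eye(self.A_x.shape[0]) + (self.A_x * self.prec_x) @ self.A_x.T
        Wx = np.linalg.solve(Px, (self.A_x * self.prec_x)).T
        self.model.encoder_x = make_affine_gaussian_net(
            Wx, -self.c_x @ Wx, np.diag(Px) / variance_inflation)


def make_linear_gaussian_jmi(d_x=2, d_k=3, d_z=1, lambda0=1.0, seed=0,
                             exact_encoders=True,
                             variance_inflation=1.0) -> LinearGaussianJMI:
    """Build a random affine instance (deterministic given seed)."""
    rng = np.random.default_rng(seed)
    A_x = rng.standard_normal((d_z, d_x))
    A_k = rng.standard_normal((d_z, d_k))
    if d_z > 1:
        # orthogonalize loadings so the posterior precision is diagonal
        B = np.concatenate([A_x, A_k], axis=1)
        Q = np.linalg.qr(B.T)[0][:, :d_z].T
        B = Q * np.linalg.norm(B, axis=1, keepdims=True)
        A_x, A_k = B[:, :d_x], B[:, d_x:]
    c_x = rng.standard_normal(d_x)
    c_k = rng.standard_normal(d_k)
    prec_x = np.full(d_x, 2.0)
    prec_k = np.full(d_k, 1.5)
    model = build_model(d_x, d_k, d_z, hidden=(8,), lambda0_init=lambda0, seed=seed)
    model.decoder_x = make_affine_gaussian_net(A_x, c_x, prec_x)
    model.decoder_k = make_affine_gaussian_net(A_k, c_k, prec_k)
    lg = LinearGaussianJMI(model, A_x, c_x, prec_x, A_k, c_k, prec_k)
    if exact_encoders:
        lg.set_exact_encoders(variance_inflation)
    return lg


def sample_log_weights(lg: LinearGaussianJMI, x, k, L, n_rep, seed=0, which="xk"):
    """(n_rep, L) log importance weights under the current encoders —
    vectorized for Monte-Carlo replication studies."""
    rng = np.random.default_rng(seed)
    model = lg.model
    if which == "xk":
        u = np.concatenate([np.atleast_1d(x), np.atleast_1d(k)])
        enc = model.encoder_xk
    else:
        u = np.atleast_1d(x)
        enc = model.encoder_x
    em, ep = enc.forward_np(u[None, :])
    em, ep = em[0], ep[0]
    z = em + rng.standard_normal((n_rep, L, model.d_z)) / np.sqrt(ep)
    log_q = _diag_logpdf(z, em, ep)
    log_pz = _diag_logpdf(z, np.zeros(model.d_z), np.ones(model.d_z))
    xm, xp = model.decoder_x.forward_np(z.reshape(-1, model.d_z))
    log_px = _diag_logpdf(np.atleast_1d(x), xm.reshape(n_rep, L, -1), xp.reshape(n_rep, L, -1))
    lw = log_px + log_pz - log_q
    if which == "xk":
        km, kp = model.decoder_k.forward_np(z.reshape(-1, model.d_z))
        lw = lw + _diag_logpdf(np.atleast_1d(k), km.reshape(n_rep, L, -1),
                               kp.reshape(n_rep, L, -1))
    return lw


def _diag_logpdf(u, mean, prec):
    resid = u - mean
    d = np.shape(u)[-1] if np.ndim(u) else 1
    return 0.5 * (np.sum(np.log(prec) * np.ones_like(resid), axis=-1)
                  - np.sum(prec * resid ** 2, axis=-1)) - 0.5 * d * np.log(2 * np.pi)
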