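"""VAE-based joint mark intensity model.

The joint mark intensity is decomposed into a positive base rate and a
latent-variable density,

    lambda(x, kappa) = lambda0 * int p(x, kappa | z) p(z) dz,

with p(x, kappa | z) = p(x|z) p(kappa|z) a product of Gaussian networks
(x and kappa conditionally independent given z), a standard-normal prior
over z, and two Gaussian-network encoders q(z|x,kappa) and q(z|x) used
as importance proposals in the Renyi / chi bounds.  Because the decoder
factorizes, the ground intensity lambda(x) = lambda0 * int p(x|z)p(z)dz
needed by the negative term of the likelihood is directly available.

This module covers the observed-state setting: the state at spike times
and on the covariate grid is known, and the model is fitted by
maximizing the combined Monte-Carlo bound with Adam and validation
early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .bounds import BoundConfig, chi_term_value
from .nets import (Adam, GaussianNet, collect_state, diag_gaussian_logpdf,
                   load_state, sample_diag_gaussian, std_normal_logpdf)


class JointMarkIntensityVAE:
    """lambda0 + decoder/prior/encoder Gaussian networks defining lambda(x, kappa)."""

    def __init__(self, d_x, d_k, d_z, hidden=(64, 64), lambda0_init=1.0, seed=0,
                 bound_cfg: BoundConfig | None = None, x_prec_cap=100.0):
        if min(d_x, d_k, d_z) < 1:
            raise ValueError("dimensions must be >= 1")
        rng = np.random.default_rng(seed)
        self.d_x, self.d_k, self.d_z = int(d_x), int(d_k), int(d_z)
        self.log_lambda0 = ad.parameter(np.log(float(lambda0_init)))
        # the cap on the x-decoder precision bounds how fast the intensity
        # can decay away from the latent manifold (keeps MAP decoding from
        # being repelled to zero-intensity regions by silent bins)
        self.decoder_x = GaussianNet(d_z, d_x, hidden, rng, prec_cap=x_prec_cap)
        self.decoder_k = GaussianNet(d_z, d_k, hidden, rng)
        self.encoder_xk = GaussianNet(d_x + d_k, d_z, hidden, rng)
        self.encoder_x = GaussianNet(d_x, d_z, hidden, rng)
        self.bound_cfg = bound_cfg or BoundConfig()

    # ------------------------------------------------------------------
    @property
    def lambda0(self) -> float:
        return float(np.exp(self.log_lambda0.value))

    def parameters(self):
        return ([self.log_lambda0] + self.decoder_x.parameters() + self.decoder_k.parameters()
                + self.encoder_xk.parameters() + self.encoder_x.parameters())

    def encoder_parameters(self):
        return self.encoder_xk.parameters() + self.encoder_x.parameters()

    def _objs(self):
        return {"log_lambda0": self.log_lambda0, "decoder_x": self.decoder_x,
                "decoder_k": self.decoder_k, "encoder_xk": self.encoder_xk,
                "encoder_x": self.encoder_x}

    def state_dict(self):
        return collect_state(self._objs())

    def load_state_dict(self, d):
        load_state(self._objs(), d)

    def save(self, path):
        """Single-file checkpoint (npz) with a config echo."""
        meta = np.array([self.d_x, self.d_k, self.d_z], dtype=np.int64)
        cfg = self.bound_cfg
        np.savez(path, __dims__=meta,
                 __bounds__=np.array([cfg.alpha, cfg.beta, cfg.L,
                                      float(cfg.use_jackknife), float(cfg.use_dreg)]),
                 __hidden_dec__=np.array(self.decoder_x.hidden, dtype=np.int64),
                 **self.state_dict())

    @classmethod
    def load(cls, path):
        with np.load(path) as f:
            d_x, d_k, d_z = (int(v) for v in f["__dims__"])
            a, b, L, jk, dreg = f["__bounds__"]
            hidden = tuple(int(h) for h in f["__hidden_dec__"])
            model = cls(d_x, d_k, d_z, hidden=hidden,
                        bound_cfg=BoundConfig(alpha=float(a), beta=float(b), L=int(L),
                                              use_jackknife=bool(jk), use_dreg=bool(dreg)))
            model.load_state_dict({k: f[k] for k in f.files if not k.startswith("__")})
        return model

    # -- conditional log densities -------------------------------------
    def log_p_x_given_z(self, x, z):
        mean, prec = self.decoder_x(z)
        return diag_gaussian_logpdf(ad.as_tensor(x), mean, prec)

    def log_p_k_given_z(self, k, z):
        mean, prec = self.decoder_k(z)
        return diag_gaussian_logpdf(ad.as_tensor(k), mean, prec)

    def log_p_xk_given_z(self, x, k, z):
        return ad.add(self.log_p_x_given_z(x, z), self.log_p_k_given_z(k, z))

    # -- importance log-weights ----------------------------------------
    def spike_log_weights(self, x, k, eps, detach_q=False):
        """log w = log p(x,kappa|z) + log p(z) - log q(z|x,kappa) with
        reparameterized z from the (x,kappa) encoder.

        x: (n, d_x), k: (n, d_k), eps: (n, L, d_z) -> (n, L).
        With ``detach_q`` the encoder outputs entering the q density are
        detached (doubly reparameterized gradient path).
        """
        xk = ad.concatenate([ad.as_tensor(x), ad.as_tensor(k)], axis=-1)
        mean, prec = self.encoder_xk(xk)
        mean_b, prec_b = _expand_mid(mean), _expand_mid(prec)
        z = sample_diag_gaussian(mean_b, prec_b, eps)
        qm, qp = (ad.stop_gradient(mean_b), ad.stop_gradient(prec_b)) if detach_q else (mean_b, prec_b)
        log_q = diag_gaussian_logpdf(z, qm, qp)
        xb = _expand_mid(ad.as_tensor(x))
        kb = _expand_mid(ad.as_tensor(k))
        return ad.add(ad.add(self.log_p_xk_given_z(xb, kb, z), std_normal_logpdf(z)),
                      ad.mul(log_q, -1.0))

    def state_log_weights(self, x, eps, detach_q=False):
        """log v = log p(x|z) + log p(z) - log q(z|x); x: (m, d_x), eps (m, L, d_z)."""
        mean, prec = self.encoder_x(ad.as_tensor(x))
        mean_b, prec_b = _expand_mid(mean), _expand_mid(prec)
        z = sample_diag_gaussian(mean_b, prec_b, eps)
        qm, qp = (ad.stop_gradient(mean_b), ad.stop_gradient(prec_b)) if detach_q else (mean_b, prec_b)
        log_q = diag_gaussian_logpdf(z, qm, qp)
        xb = _expand_mid(ad.as_tensor(x))
        return ad.add(ad.add(self.log_p_x_given_z(xb, z), std_normal_logpdf(z)),
                      ad.mul(log_q, -1.0))


def _expand_mid(t):
    """(n, d) -> (n, 1, d) so a sample axis can broadcast in the middle."""
    v = ad.value_of(t)
    return ad.reshape(t, (v.shape[0], 1, v.shape[1])) if isinstance(t, ad.Tensor) else v[:, None, :]


def build_model(d_x, d_k, d_z, hidden=(64, 64), lambda0_init=1.0, seed=0,
                bound_cfg=None, x_prec_cap=100.0) -> JointMarkIntensityVAE:
    """Deterministically initialized model (same seed -> same parameters)."""
    return JointMarkIntensityVAE(d_x, d_k, d_z, hidden=hidden,
                                 lambda0_init=lambda0_init, seed=seed,
                                 bound_cfg=bound_cfg, x_prec_cap=x_prec_cap)


# ---------------------------------------------------------------------------
# intensity estimates
# ---------------------------------------------------------------------------

def intensity_estimate(model, x, k, S: int, seed=0, proposal="encoder") -> float:
    """Monte-Carlo estimate of lambda(x, kappa).

    ``proposal='encoder'`` uses importance sampling from q(z|x,kappa)
    (the trained proposal); ``'prior'`` averages the decoder density over
    prior draws — the simple consistent oracle.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    k = np.atleast_2d(np.asarray(k, dtype=np.float64))
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(k))):
        raise ValueError("non-finite inputs")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((x.shape[0], S, model.d_z))
    if proposal == "prior":
        z = ad.Tensor(eps)
        lw = ad.value_of(model.log_p_xk_given_z(_expand_mid(ad.as_tensor(x)),
                                                _expand_mid(ad.as_tensor(k)), z))
    else:
        lw = ad.value_of(model.spike_log_weights(x, k, ad.Tensor(eps)))
    est = model.lambda0 * np.exp(ad.logsumexp(lw, axis=-1) - np.log(S))
    return float(est[0]) if est.size == 1 else est


def ground_intensity_estimate(model, x, S: int, seed=0, proposal="encoder") -> float:
    """Monte-Carlo estimate of the ground intensity lambda(x)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite inputs")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((x.shape[0], S, model.d_z))
    if proposal == "prior":
        z = ad.Tensor(eps)
        lw = ad.value_of(model.log_p_x_given_z(_expand_mid(ad.as_tensor(x)), z))
    else:
        lw = ad.value_of(model.state_log_weights(x, ad.Tensor(eps)))
    est = model.lambda0 * np.exp(ad.logsumexp(lw, axis=-1) - np.log(S))
    return float(est[0]) if est.size == 1 else est


# ---------------------------------------------------------------------------
# the combined bound (Monte Carlo) and fitting
# ---------------------------------------------------------------------------

def mc_bound(model, states_at_spikes, spike_marks, states_at_grid, cfg=None,
             dt=1.0, absorb_dt=False, rng=None, eps_pair=None, dreg=False):
    """Monte-Carlo value of the combined point-process bound.

    Returns the bound tensor, or (bound, encoder_surrogate) when ``dreg``
    (alpha = 1 doubly reparameterized path for the spike terms).
    The grid spacing dt multiplies the chi (integral) term unless it has
    been absorbed into lambda0 (``absorb_dt``).
    """
    cfg = cfg or model.bound_cfg
    xs = np.atleast_2d(np.asarray(states_at_spikes, dtype=np.float64))
    ks = np.atleast_2d(np.asarray(spike_marks, dtype=np.float64))
    xg = np.atleast_2d(np.asarray(states_at_grid, dtype=np.float64))
    n, m = (xs.shape[0] if ks.size else 0), xg.shape[0]
    if eps_pair is None:
        rng = rng or np.random.default_rng(0)
        eps_pair = (rng.standard_normal((max(n, 1), cfg.L, model.d_z)),
                    rng.standard_normal((m, cfg.L, model.d_z)))
    eps_s, eps_g = eps_pair
    log_dt = 0.0 if absorb_dt else float(np.log(dt))
    # chi / integral side
    lv = model.state_log_weights(xg, ad.Tensor(eps_g))
    chi = chi_term_value(lv, cfg.beta, ad.add(model.log_lambda0, log_dt),
                         jackknife=cfg.use_jackknife and cfg.L >= 2)
    bound = ad.mul(ad.tsum(chi), -1.0)
    if n > 0:
        lw = model.spike_log_weights(xs, ks, ad.Tensor(eps_s))
        shifted = ad.add(lw, model.log_lambda0)
        per_spike = ad.mul(ad.logsumexp(ad.mul(shifted, cfg.alpha), axis=-1), 1.0 / cfg.alpha)
        bound = ad.add(bound, ad.tsum(per_spike) - n * np.log(cfg.L) / cfg.alpha)
    if not dreg:
        return bound
    if cfg.alpha != 1.0:
        raise ValueError("the doubly reparameterized path is implemented for alpha = 1")
    if n == 0:
        return bound, None
    lw_det = model.spike_log_weights(xs, ks, ad.Tensor(eps_s), detach_q=True)
    w = ad.value_of(lw_det) + model.log_lambda0.value
    wt = np.exp(w - ad.logsumexp(w, axis=-1, keepdims=True))    # normalized weights
    surrogate = ad.tsum(ad.mul(lw_det, wt ** 2))
    return bound, surrogate


def nll_bound(model, states_at_spikes, spike_marks, states_at_grid, cfg=None,
              dt=1.0, absorb_dt=False, seed=0) -> float:
    """Negative of the Monte-Carlo bound: an *upper* bound on the true NLL."""
    cfg = cfg or model.bound_cfg
    b = mc_bound(model, states_at_spikes, spike_marks, states_at_grid, cfg,
                 dt=dt, absorb_dt=absorb_dt, rng=np.random.default_rng(seed))
    return -float(ad.value_of(b))


@dataclass
class TrainConfig:
    epochs: int = 100
    lr: float = 1e-3
    patience: int = 15
    seed: int = 0
    val_fraction: float = 0.1
    dt: float = 1.0
    absorb_dt: bool = False
    init_lambda0_from_rate: bool = True
    verbose: bool = False


def fit_observed_state(model, states_at_spikes, spike_marks, states_at_grid,
                       cfg: TrainConfig = None, val_data=None):
    """Maximize the combined bound with Adam + validation early stopping.

    ``val_data`` is an optional (states_at_spikes, marks, states_at_grid)
    triple; otherwise a contiguous tail of the grid (and the spikes whose
    index falls there, by proportion) is held out.

    Returns (model, trace) where trace has per-epoch train/val bounds;
    the best-validation parameters are restored in the model.
    """
    cfg = cfg or TrainConfig()
    xs = np.atleast_2d(np.asarray(states_at_spikes, dtype=np.float64))
    ks = np.atleast_2d(np.asarray(spike_marks, dtype=np.float64))
    xg = np.atleast_2d(np.asarray(states_at_grid, dtype=np.float64))
    if val_data is None:
        n_val_g = max(1, int(round(cfg.val_fraction * xg.shape[0])))
        n_val_s = int(round(cfg.val_fraction * xs.shape[0]))
        val_data = (xs[xs.shape[0] - n_val_s:], ks[ks.shape[0] - n_val_s:], xg[xg.shape[0] - n_val_g:])
        xs, ks = xs[:xs.shape[0] - n_val_s], ks[:ks.shape[0] - n_val_s]
        xg = xg[:xg.shape[0] - n_val_g]
    if cfg.init_lambda0_from_rate and xs.shape[0] > 0:
        total_t = xg.shape[0] * (1.0 if cfg.absorb_dt else cfg.dt)
        model.log_lambda0.value = np.array(np.log(max(xs.shape[0], 1) / total_t))
    rng = np.random.default_rng(cfg.seed)
    bcfg = model.bound_cfg
    opt = Adam(model.parameters(), lr=cfg.lr)
    enc_params = {id(p) for p in model.encoder_parameters()}
    trace = {"train": [], "val": []}
    best_val, best_state, since_best = -np.inf, model.state_dict(), 0
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        out = mc_bound(model, xs, ks, xg, bcfg, dt=cfg.dt, absorb_dt=cfg.absorb_dt,
                       rng=rng, dreg=bcfg.use_dreg)
        bound, surrogate = out if isinstance(out, tuple) else (out, None)
        bval = float(ad.value_of(bound))
        if not np.isfinite(bval):
            raise RuntimeError(
                f"diverged objective at epoch {epoch}: bound={bval}, lambda0={model.lambda0:.3g}")
        bound.backward()
        if surrogate is not None:
            # DReG replaces the encoder gradients; all other gradients keep
            # the plain reparameterized estimate.
            saved = {id(p): p.grad for p in model.parameters() if id(p) not in enc_params}
            for p in model.parameters():
                p.grad = None
            surrogate.backward()
            for p in model.parameters():
                if id(p) not in enc_params:
                    p.grad = saved[id(p)]
        opt.step(maximize=True)
        vb = mc_bound(model, *val_data, bcfg, dt=cfg.dt, absorb_dt=cfg.absorb_dt,
                      rng=np.random.default_rng(cfg.seed + 10_000))
        vval = float(ad.value_of(vb))
        trace["train"].append(bval)
        trace["val"].append(vval)
        if vval > best_val:
            best_val, best_state, since_best = vval, model.state_dict(), 0
        else:
            since_best += 1
            if since_best > cfg.patience:
                break
        if cfg.verbose:
            print(f"epoch {epoch}: train {bval:.3f} val {vval:.3f}")
    model.load_state_dict(best_state)
    return model, trace
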