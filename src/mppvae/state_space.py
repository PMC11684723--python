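"""Black-box state-space model with a marked-point-process observation.

Generative side: linear-Gaussian latent dynamics x_r, a Gaussian-network
observation model p(y_r|x_r), and the VAE joint mark intensity as the
observation model for the per-bin mark sets kappa_r.  Inference uses a
structured variational family — Markov chain factors q(x_1), q(x_r|x_{r-1})
times per-bin Gaussian experts from y_r and from each spike mark — whose
product is a Gaussian with block-tridiagonal precision, so sampling and
densities cost O(R).  Training maximizes the ELBO with the per-bin
point-process term replaced by its Renyi/chi Monte-Carlo bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import block_tridiag as bt
from .bounds import BoundConfig, chi_term_value
from .core_data import BinnedDataset
from .jmi_vae import JointMarkIntensityVAE, _expand_mid
from .nets import (Adam, GaussianNet, collect_state, diag_gaussian_logpdf,
                   load_state, LOG2PI)

log_ = logging.getLogger(__name__)


def _softplus_inv(y):
    y = np.maximum(np.asarray(y, dtype=np.float64), 1e-12)
    return np.where(y > 30, y, np.log(np.expm1(np.minimum(y, 30.0))))


class SPDParam:
    """Unconstrained parameterization of an SPD matrix via its Cholesky
    factor (softplus-positive diagonal)."""

    def __init__(self, d, init=None):
        self.d = d
        if init is None:
            M = np.zeros((d, d))
        else:
            L = np.linalg.cholesky(np.asarray(init, dtype=np.float64))
            M = np.tril(L, -1) + np.diag(_softplus_inv(np.diag(L)))
        self.M = ad.parameter(M)
        self._eye = np.eye(d)
        self._strict = np.tril(np.ones((d, d)), -1)

    def chol(self):
        dd = ad.softplus(self.M[(np.arange(self.d), np.arange(self.d))])
        return ad.add(ad.mul(self.M, self._strict), ad.mul(self._eye, dd))

    def matrix(self):
        L = self.chol()
        return ad.matmul(L, ad.swap_last(L))

    def logdet(self):
        dd = ad.softplus(self.M[(np.arange(self.d), np.arange(self.d))])
        return ad.mul(ad.tsum(ad.log(dd)), 2.0)

    def parameters(self):
        return [self.M]


class LinearGaussianDynamics:
    """x_1 ~ N(a1, V1^-1);  x_r | x_{r-1} ~ N(F x_{r-1} + a, V^-1).

    V1, V are precision matrices (SPD by construction).  Used for both
    the generative dynamics (a1, V1, F, a, V) and, with its own
    parameters, the variational chain (b1, W1, G, b, W).
    """

    def __init__(self, d, F_scale=0.99):
        self.d = d
        self.a1 = ad.parameter(np.zeros(d))
        self.V1p = SPDParam(d, np.eye(d))
        self.F = ad.parameter(F_scale * np.eye(d))
        self.a = ad.parameter(np.zeros(d))
        self.Vp = SPDParam(d, np.eye(d))

    @classmethod
    def from_matrices(cls, a1, V1, F, a, V):
        d = len(np.asarray(a1))
        dyn = cls(d)
        dyn.a1.value = np.asarray(a1, dtype=np.float64)
        dyn.V1p = SPDParam(d, V1)
        dyn.F.value = np.asarray(F, dtype=np.float64)
        dyn.a.value = np.asarray(a, dtype=np.float64)
        dyn.Vp = SPDParam(d, V)
        return dyn

    def parameters(self):
        return [self.a1, self.F, self.a] + self.V1p.parameters() + self.Vp.parameters()

    def log_density_path(self, x):
        """log p(x_1..x_R) for a path tensor (R, d)."""
        d = self.d
        V1 = self.V1p.matrix()
        V = self.Vp.matrix()
        r0 = ad.add(x[0], ad.mul(self.a1, -1.0))
        quad0 = ad.tsum(ad.mul(r0, ad.matmul(V1, r0)))
        out = ad.add(ad.mul(self.V1p.logdet(), 0.5), ad.mul(ad.add(quad0, d * LOG2PI), -0.5))
        R = ad.value_of(x).shape[0]
        if R > 1:
            pred = ad.add(ad.matmul(x[:-1], ad.swap_last(self.F)), self.a)
            resid = ad.add(x[1:], ad.mul(pred, -1.0))
            quad = ad.tsum(ad.mul(resid, ad.matmul(resid, self.Vp.matrix())))
            out = ad.add(out, ad.add(ad.mul(self.Vp.logdet(), 0.5 * (R - 1)),
                                     ad.mul(ad.add(quad, (R - 1) * d * LOG2PI), -0.5)))
        return out


class StateSpaceModel:
    """p(x) p(y|x) p(kappa|x) with the VAE joint mark intensity."""

    def __init__(self, d_x, d_y, jmi: JointMarkIntensityVAE, hidden=(64, 64), seed=0):
        if jmi.d_x != d_x:
            raise ValueError("jmi state dimension must equal the hidden dimension")
        rng = np.random.default_rng(seed)
        self.d_x, self.d_y = int(d_x), int(d_y)
        self.dyn = LinearGaussianDynamics(d_x)
        self.obs_y = GaussianNet(d_x, d_y, hidden, rng)
        self.jmi = jmi

    def parameters(self):
        return self.dyn.parameters() + self.obs_y.parameters() + self.jmi.parameters()

    def _objs(self):
        out = {"obs_y": self.obs_y, "dyn.a1": self.dyn.a1, "dyn.F": self.dyn.F,
               "dyn.a": self.dyn.a, "dyn.V1": self.dyn.V1p.M, "dyn.V": self.dyn.Vp.M}
        for k, v in self.jmi._objs().items():
            out[f"jmi.{k}"] = v
        return out

    def state_dict(self):
        return collect_state(self._objs())

    def load_state_dict(self, d):
        load_state(self._objs(), d)


class StructuredVariationalFamily:
    """Markov chain factors + per-bin Gaussian experts (y, each spike mark,
    and a constant base expert standing in for exp(-lambda(x_r)))."""

    def __init__(self, d_x, d_y, d_k, hidden=(64, 64), seed=0):
        rng = np.random.default_rng(seed)
        self.d_x = int(d_x)
        self.qdyn = LinearGaussianDynamics(d_x)
        self.enc_y = GaussianNet(d_y, d_x, hidden, rng)
        self.enc_k = GaussianNet(d_k, d_x, hidden, rng)
        self.base_mean = ad.parameter(np.zeros(d_x))
        self.base_logprec = ad.parameter(np.full(d_x, _softplus_inv(1.0)))

    def base_expert(self):
        return self.base_mean, ad.add(ad.softplus(self.base_logprec), 1e-6)

    def parameters(self):
        return (self.qdyn.parameters() + self.enc_y.parameters() + self.enc_k.parameters()
                + [self.base_mean, self.base_logprec])

    def _objs(self):
        return {"enc_y": self.enc_y, "enc_k": self.enc_k,
                "q.a1": self.qdyn.a1, "q.F": self.qdyn.F, "q.a": self.qdyn.a,
                "q.V1": self.qdyn.V1p.M, "q.V": self.qdyn.Vp.M,
                "base_mean": self.base_mean, "base_logprec": self.base_logprec}

    def state_dict(self):
        return collect_state(self._objs())

    def load_state_dict(self, d):
        load_state(self._objs(), d)


# ---------------------------------------------------------------------------
# structured posterior assembly (information form)
# ---------------------------------------------------------------------------

def _spike_index(data: BinnedDataset):
    """Concatenate all marks; returns (marks (N, D_k), bin index (N,))."""
    idx, marks = [], []
    for r, ms in enumerate(data.mark_sets):
        if len(ms):
            idx.append(np.full(len(ms), r, dtype=int))
            marks.append(np.asarray(ms, dtype=np.float64))
    if not marks:
        return np.zeros((0, 1)), np.zeros(0, dtype=int)
    return np.concatenate(marks, axis=0), np.concatenate(idx)


def build_structured_posterior(q: StructuredVariationalFamily, data: BinnedDataset,
                               include_y=True, include_spikes=True,
                               jitter=1e-6, max_jitter_tries=3):
    """Assemble the product of chain factors and per-bin experts.

    Returns (PosteriorGaussian, BlockCholesky); mean and precision are
    autodiff tensors when any q parameter requires gradients.  Non-PD
    assemblies get ``jitter * I`` added up to ``max_jitter_tries`` times
    (logged) before failing.
    """
    R, d = data.R, q.d_x
    eye = np.eye(d)
    W1 = q.qdyn.V1p.matrix()
    W = q.qdyn.Vp.matrix()
    G = q.qdyn.F
    GtW = ad.matmul(ad.swap_last(G), W)
    GtWG = ad.matmul(GtW, G)

    diag_blocks = []
    h = [None] * R
    W1b1 = ad.matmul(W1, q.qdyn.a1)
    Wb = ad.matmul(W, q.qdyn.a)
    GtWb = ad.matmul(GtW, q.qdyn.a)
    for r in range(R):
        blk = W1 if r == 0 else W
        hr = W1b1 if r == 0 else Wb
        if r + 1 < R:
            blk = ad.add(blk, GtWG)
            hr = ad.add(hr, ad.mul(GtWb, -1.0))
        diag_blocks.append(blk)
        h[r] = hr
    D = ad.stack(diag_blocks, axis=0)                       # (R, d, d)
    hvec = ad.stack(h, axis=0)                              # (R, d)
    off = _tile(ad.mul(GtW, -1.0), R - 1) if R > 1 else ad.Tensor(np.zeros((0, d, d)))

    # per-bin experts: diagonal precisions added to the block diagonals
    base_m, base_p = q.base_expert()
    prec_sum = ad.add(ad.mul(ad.Tensor(np.ones((R, d))), 0.0), base_p)
    info_sum = ad.mul(_tile2(ad.mul(base_p, base_m), R), 1.0)
    if include_y:
        ym, yp = q.enc_y(data.y)
        prec_sum = ad.add(prec_sum, yp)
        info_sum = ad.add(info_sum, ad.mul(yp, ym))
    if include_spikes:
        marks, bin_idx = _spike_index(data)
        if len(bin_idx):
            km, kp = q.enc_k(marks)
            prec_sum = ad.add(prec_sum, ad.index_add(R, bin_idx, kp, (d,)))
            info_sum = ad.add(info_sum, ad.index_add(R, bin_idx, ad.mul(kp, km), (d,)))
    D = ad.add(D, ad.mul(eye, ad.reshape(prec_sum, (R, 1, d))))
    hvec = ad.add(hvec, info_sum)

    for attempt in range(max_jitter_tries + 1):
        P = bt.BlockTridiagonalSPD(D, off)
        try:
            factor = bt.factorize(P)
            break
        except bt.DecompositionError as err:
            if attempt == max_jitter_tries:
                raise
            log_.warning("posterior precision not PD at block %d; adding jitter", err.block_index)
            D = ad.add(D, jitter * np.eye(d))
    mean = bt.solve(factor, hvec)
    return bt.PosteriorGaussian(mean, P), factor


def _tile(t, n):
    """(d, d) tensor -> (n, d, d) by broadcasting through a zero add."""
    v = ad.value_of(t)
    return ad.add(ad.Tensor(np.zeros((n,) + v.shape)), t)


def _tile2(t, n):
    v = ad.value_of(t)
    return ad.add(ad.Tensor(np.zeros((n,) + v.shape)), t)


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------

def elbo(model: StateSpaceModel, q: StructuredVariationalFamily, data: BinnedDataset,
         n_mc=1, seed=0, bound_cfg: BoundConfig | None = None, absorb_dt=False,
         include_spike_terms=True):
    """Monte-Carlo evidence lower bound on log p(y, kappa).

    The per-bin point-process likelihood is replaced by its Renyi/chi
    bound; log q of sampled paths is evaluated exactly from the block
    factorization.  Deterministic given the seed.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    cfg = bound_cfg or model.jmi.bound_cfg
    R, d = data.R, model.d_x
    rng = np.random.default_rng(seed)
    post, factor = build_structured_posterior(q, data, include_spikes=include_spike_terms)
    logdet_q = bt.logdet(factor)
    marks, bin_idx = _spike_index(data)
    n_spk = len(bin_idx)
    log_dt = 0.0 if absorb_dt else float(np.log(data.dt_bin))
    total = None
    for s in range(n_mc):
        eps = rng.standard_normal((R, d, 1))
        u = bt.sample_noise(factor, eps)
        x = ad.add(post.mean, ad.reshape(u, (R, d)))
        # -log q(x_s): exact; the quadratic form is eps'eps by construction
        neg_log_q = ad.add(ad.mul(logdet_q, -0.5),
                           0.5 * R * d * LOG2PI + 0.5 * float(np.sum(eps ** 2)))
        term = ad.add(model.dyn.log_density_path(x), neg_log_q)
        ym, yp = model.obs_y(x)
        term = ad.add(term, ad.tsum(diag_gaussian_logpdf(ad.Tensor(data.y), ym, yp)))
        if include_spike_terms:
            # chi (integral) term at every bin
            eps_g = rng.standard_normal((R, cfg.L, model.jmi.d_z))
            lv = model.jmi.state_log_weights(x, ad.Tensor(eps_g))
            chi = chi_term_value(lv, cfg.beta, ad.add(model.jmi.log_lambda0, log_dt),
                                 jackknife=cfg.use_jackknife and cfg.L >= 2)
            term = ad.add(term, ad.mul(ad.tsum(chi), -1.0))
            if n_spk:
                x_at_spk = x[bin_idx]
                eps_s = rng.standard_normal((n_spk, cfg.L, model.jmi.d_z))
                lw = model.jmi.spike_log_weights(x_at_spk, marks, ad.Tensor(eps_s))
                shifted = ad.add(lw, model.jmi.log_lambda0)
                per_spike = ad.mul(ad.logsumexp(ad.mul(shifted, cfg.alpha), axis=-1), 1.0 / cfg.alpha)
                term = ad.add(term, ad.tsum(per_spike) - n_spk * np.log(cfg.L) / cfg.alpha)
        total = term if total is None else ad.add(total, term)
    out = ad.mul(total, 1.0 / n_mc)
    if not np.isfinite(ad.value_of(out)):
        raise RuntimeError(f"diverged ELBO (lambda0={model.jmi.lambda0:.3g})")
    return out


def predict_nll(model, q, data: BinnedDataset, n_mc=8, seed=0, **kw) -> float:
    """Negative ELBO of held-out (y, kappa): an upper bound on the true NLL."""
    return -float(ad.value_of(elbo(model, q, data, n_mc=n_mc, seed=seed, **kw)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class SSMTrainConfig:
    epochs: int = 30
    lr: float = 3e-3
    patience: int = 8
    seed: int = 0
    segment_len: int = 200
    n_mc: int = 1
    val_n_mc: int = 4
    init_lambda0_from_rate: bool = True
    # step decay: lr multiplied by the factor at these epoch fractions
    lr_decay_at: tuple = (0.6, 0.85)
    lr_decay_factor: float = 0.3
    verbose: bool = False


def _segments(R, seg_len):
    """Contiguous segments with 1-bin overlap covering [0, R)."""
    if R <= seg_len:
        return [(0, R)]
    out, start = [], 0
    while start < R - 1:
        stop = min(start + seg_len, R)
        out.append((start, stop))
        if stop == R:
            break
        start = stop - 1
    return out


def fit(model: StateSpaceModel, q: StructuredVariationalFamily, data: BinnedDataset,
        cfg: SSMTrainConfig = None, val_data: BinnedDataset = None):
    """Maximize the ELBO over all parameters simultaneously (Adam), with
    per-epoch passes over contiguous segments and validation early
    stopping.  Non-initial segments reuse the initial-distribution factor
    at their first bin.  Returns (model, q, trace)."""
    cfg = cfg or SSMTrainConfig()
    if cfg.epochs == 0:
        return model, q, {"train": [], "val": []}
    if cfg.init_lambda0_from_rate:
        rate = max(data.total_events, 1) / (data.R * data.dt_bin)
        model.jmi.log_lambda0.value = np.array(np.log(rate))
    segs = _segments(data.R, cfg.segment_len)
    params = model.parameters() + q.parameters()
    opt = Adam(params, lr=cfg.lr)
    trace = {"train": [], "val": []}
    best_val, best_state, since_best = -np.inf, (model.state_dict(), q.state_dict()), 0
    rng = np.random.default_rng(cfg.seed)
    decay_epochs = {int(f * cfg.epochs) for f in cfg.lr_decay_at}
    for epoch in range(cfg.epochs):
        if epoch in decay_epochs:
            opt.lr *= cfg.lr_decay_factor
        tot = 0.0
        for (a, b) in segs:
            opt.zero_grad()
            sub = data.slice(a, b)
            e = elbo(model, q, sub, n_mc=cfg.n_mc, seed=int(rng.integers(2 ** 31 - 1)))
            e.backward()
            opt.step(maximize=True)
            tot += float(ad.value_of(e))
        trace["train"].append(tot)
        if val_data is not None:
            v = float(ad.value_of(elbo(model, q, val_data, n_mc=cfg.val_n_mc,
                                       seed=cfg.seed + 999)))
        else:
            v = tot
        trace["val"].append(v)
        if cfg.verbose:
            print(f"epoch {epoch}: train {tot:.2f} val {v:.2f}")
        if v > best_val:
            best_val, best_state, since_best = v, (model.state_dict(), q.state_dict()), 0
        else:
            since_best += 1
            if since_best > cfg.patience:
                break
    model.load_state_dict(best_state[0])
    q.load_state_dict(best_state[1])
    return model, q, trace
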