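"""GMM joint-mark-intensity baseline and the model-comparison harness.

The baseline defines the joint mark intensity as a Gaussian mixture with
per-component scales,

    lambda(x, kappa) = sum_l lambda_l N(x | mu_l^x, P_l^x) N(kappa | mu_l^k, P_l^k),

whose kappa-marginal (the ground intensity) is closed-form, so the
discretized point-process log-likelihood is exact — no variational
bounds.  Fitting is gradient ascent on that exact objective over
log-scales, means, and log diagonal precisions (KMeans-seeded).

Decoding reuses the same concavified-Newton machinery as the VAE model:
the mixture log-intensity is a log-sum-exp of concave quadratics and the
negative ground intensity is a negative sum of exponentials of concave
quadratics, so the Gauss-Newton composite linearization applies with the
mixture components playing the role of the frozen samples.

The comparison harness runs paired Wilcoxon signed-rank tests on
per-trial (or per-fold) scores and adjusts the p-values with the
Holm-Sidak step-down method; significance is declared at p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from . import autodiff as ad
from .core_data import BinnedDataset
from .decoding import ChiStateTerm, RenyiSpikeTerm
from .nets import Adam, LOG2PI

log_ = logging.getLogger(__name__)

LOG_PREC_CAP = np.log(1e4)


@dataclass
class GMMIntensity:
    """Mixture parameters; diagonal precisions in both spaces."""

    lambdas: np.ndarray   # (L_c,)
    mu_x: np.ndarray      # (L_c, d_x)
    prec_x: np.ndarray    # (L_c, d_x)
    mu_k: np.ndarray      # (L_c, D_k)
    prec_k: np.ndarray    # (L_c, D_k)

    def __post_init__(self):
        for name in ("lambdas", "mu_x", "prec_x", "mu_k", "prec_k"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if np.any(self.lambdas <= 0) or np.any(self.prec_x <= 0) or np.any(self.prec_k <= 0):
            raise ValueError("scales and precisions must be positive")

    @property
    def n_components(self):
        return len(self.lambdas)


def _diag_lognorm(u, mu, prec):
    """log N per (point, component) with diagonal precision; u (n, D),
    mu/prec (L, D) -> (n, L)."""
    resid = u[:, None, :] - mu[None, :, :]
    return 0.5 * (np.sum(np.log(prec), axis=-1)[None, :]
                  - np.einsum("nld,ld->nl", resid ** 2, prec)) - 0.5 * u.shape[-1] * LOG2PI


def gmm_intensity(g: GMMIntensity, x, k):
    """Exact lambda(x, kappa); x (d,) or (n, d), k likewise."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    k = np.atleast_2d(np.asarray(k, dtype=np.float64))
    if x.shape[0] != k.shape[0]:
        raise ValueError("x and k batch sizes disagree")
    lg = np.log(g.lambdas)[None, :] + _diag_lognorm(x, g.mu_x, g.prec_x) \
        + _diag_lognorm(k, g.mu_k, g.prec_k)
    out = np.exp(ad.logsumexp(lg, axis=-1))
    return float(out[0]) if out.size == 1 else out


def gmm_ground_intensity(g: GMMIntensity, x):
    """Exact kappa-marginal lambda(x) = sum_l lambda_l N(x|mu_l, P_l)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    lg = np.log(g.lambdas)[None, :] + _diag_lognorm(x, g.mu_x, g.prec_x)
    out = np.exp(ad.logsumexp(lg, axis=-1))
    return float(out[0]) if out.size == 1 else out


def gmm_loglik(g: GMMIntensity, states_at_spikes, spike_marks, states_at_grid, dt=1.0):
    """Exact discretized point-process log-likelihood (the reference
    objective; no bounds)."""
    xs = np.atleast_2d(states_at_spikes)
    term = 0.0
    if xs.size:
        term += float(np.sum(np.log(gmm_intensity(g, xs, np.atleast_2d(spike_marks)))))
    term -= dt * float(np.sum(gmm_ground_intensity(g, np.atleast_2d(states_at_grid))))
    return term


# ---------------------------------------------------------------------------
# fitting (gradient ascent on the exact objective)
# ---------------------------------------------------------------------------

def gmm_fit(states_at_spikes, spike_marks, states_at_grid, n_components=16,
            dt=1.0, n_iter=400, lr=0.05, seed=0, init=None, verbose=False):
    """Maximize the exact log-likelihood over mixture parameters.

    KMeans on the marks seeds the components (component states from the
    assigned spikes' states); precisions are capped at 1e4 with a
    warning on collapse.  Returns (GMMIntensity, objective trace).
    """
    xs = np.atleast_2d(np.asarray(states_at_spikes, dtype=np.float64))
    ks = np.atleast_2d(np.asarray(spike_marks, dtype=np.float64))
    xg = np.atleast_2d(np.asarray(states_at_grid, dtype=np.float64))
    n, d = xs.shape
    L_c = int(n_components)
    if L_c < 1:
        raise ValueError("n_components must be >= 1")
    if init is None:
        init = _kmeans_init(xs, ks, xg, L_c, dt, seed)
    p_loglam = ad.parameter(np.log(init.lambdas))
    p_mux = ad.parameter(init.mu_x.copy())
    p_lpx = ad.parameter(np.log(init.prec_x))
    p_muk = ad.parameter(init.mu_k.copy())
    p_lpk = ad.parameter(np.log(init.prec_k))
    params = [p_loglam, p_mux, p_lpx, p_muk, p_lpk]
    opt = Adam(params, lr=lr)
    trace = []

    def lognorm_t(u, mu, lp):
        D = u.shape[-1]
        prec = ad.exp(ad.minimum_const(lp, LOG_PREC_CAP))
        resid = ad.add(np.ascontiguousarray(u[:, None, :]), ad.mul(ad.reshape(mu, (1, L_c, D)), -1.0))
        quad = ad.tsum(ad.mul(ad.mul(resid, resid), ad.reshape(prec, (1, L_c, D))), axis=-1)
        ld = ad.reshape(ad.tsum(ad.log(prec), axis=-1), (1, L_c))
        return ad.mul(ad.add(ld, ad.mul(quad, -1.0)), 0.5) - 0.5 * D * LOG2PI

    for it in range(n_iter + 1):
        opt.zero_grad()
        lg_grid = ad.add(ad.reshape(p_loglam, (1, L_c)), lognorm_t(xg, p_mux, p_lpx))
        obj = ad.mul(ad.tsum(ad.exp(ad.minimum_const(lg_grid, 50.0))), -dt)
        if n:
            lg_spk = ad.add(ad.add(ad.reshape(p_loglam, (1, L_c)), lognorm_t(xs, p_mux, p_lpx)),
                            lognorm_t(ks, p_muk, p_lpk))
            obj = ad.add(obj, ad.tsum(ad.logsumexp(lg_spk, axis=-1)))
        trace.append(float(ad.value_of(obj)))
        if it == n_iter:
            break
        obj.backward()
        opt.step(maximize=True)
    if np.any(p_lpx.value > LOG_PREC_CAP) or np.any(p_lpk.value > LOG_PREC_CAP):
        log_.warning("component precision hit the cap (collapse guard)")
    g = GMMIntensity(np.exp(p_loglam.value), p_mux.value,
                     np.exp(np.minimum(p_lpx.value, LOG_PREC_CAP)),
                     p_muk.value, np.exp(np.minimum(p_lpk.value, LOG_PREC_CAP)))
    if verbose:
        print(f"gmm_fit: {trace[0]:.2f} -> {trace[-1]:.2f}")
    return g, trace


def _kmeans_init(xs, ks, xg, L_c, dt, seed):
    n = xs.shape[0]
    total_time = xg.shape[0] * dt
    if n >= L_c:
        km = KMeans(n_clusters=L_c, n_init=3, random_state=seed).fit(ks)
        lab = km.labels_
    else:
        lab = np.zeros(n, dtype=int)
    mu_x = np.empty((L_c, xs.shape[1]))
    prec_x = np.empty_like(mu_x)
    mu_k = np.empty((L_c, ks.shape[1]))
    prec_k = np.empty_like(mu_k)
    lam = np.empty(L_c)
    gvar_x = xg.var(axis=0) + 1e-3
    gvar_k = ks.var(axis=0) + 1e-3 if n else np.ones(ks.shape[1])
    for l in range(L_c):
        sel = lab == l
        cnt = sel.sum()
        lam[l] = max(cnt, 0.5) / total_time
        if cnt:
            mu_x[l] = xs[sel].mean(axis=0)
            prec_x[l] = 1.0 / (xs[sel].var(axis=0) + 0.1 * gvar_x)
            mu_k[l] = ks[sel].mean(axis=0)
            prec_k[l] = 1.0 / (ks[sel].var(axis=0) + 0.05 * gvar_k)
        else:
            mu_x[l] = xg.mean(axis=0)
            prec_x[l] = 1.0 / gvar_x
            mu_k[l] = ks.mean(axis=0) if n else 0.0
            prec_k[l] = 1.0 / gvar_k
    return GMMIntensity(lam, mu_x, prec_x, mu_k, prec_k)


# ---------------------------------------------------------------------------
# decoding provider (concavified Newton over the GMM objective)
# ---------------------------------------------------------------------------

class GMMBinTermProvider:
    """Per-bin terms for Newton MAP decoding with the GMM intensity.

    The mixture components act as the frozen 'samples': the spike term is
    log sum_l exp(g_l(x)) (concave outer log of positive inner values)
    and the integral term is -sum_l exp(h_l(x)) with h_l concave
    quadratics, both linearized by the same Gauss-Newton composites.
    """

    def __init__(self, gmm: GMMIntensity, data: BinnedDataset, absorb_dt=False):
        self.g = gmm
        self.data = data
        self.log_dt = 0.0 if absorb_dt else float(np.log(data.dt_bin))

    def expand(self, x_bar, rng):
        g, data = self.g, self.data
        R = data.R
        L_c = g.n_components
        terms = [[] for _ in range(R)]
        lgx = np.log(g.lambdas)[None, :] + _diag_lognorm(x_bar, g.mu_x, g.prec_x)  # (R, L_c)
        grads = g.prec_x[None, :, :] * (g.mu_x[None, :, :] - x_bar[:, None, :])    # (R, L_c, d)
        for r in range(R):
            # integral term: -dt * lambda(x) = -sum_l exp(h_l)
            h = lgx[r] + self.log_dt + np.log(L_c)   # ChiStateTerm(beta=1) divides by L
            terms[r].append(ChiStateTerm(1.0, h, grads[r], x_bar[r],
                                         dec_mean=g.mu_x, dec_prec=g.prec_x))
            if data.counts[r]:
                ksr = np.asarray(data.mark_sets[r], dtype=np.float64)
                lgk = _diag_lognorm(ksr, g.mu_k, g.prec_k)       # (n_r, L_c)
                for i in range(data.counts[r]):
                    lw = lgx[r] + lgk[i] + np.log(L_c)           # alpha=1 Renyi: mean -> sum
                    terms[r].append(RenyiSpikeTerm(1.0, lw, grads[r], x_bar[r],
                                                   dec_mean=g.mu_x, dec_prec=g.prec_x))
        return terms


# ---------------------------------------------------------------------------
# paired statistical comparison
# ---------------------------------------------------------------------------

def wilcoxon_holm_sidak(scores: pd.DataFrame, alternative="two-sided") -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank tests with Holm-Sidak adjustment.

    `scores`: rows = trials/folds, columns = models, entries = metric
    values (no missing entries).  Returns a tidy frame with raw and
    adjusted p per model pair; adjusted p is monotone in rank and >= raw.
    """
    if isinstance(scores, pd.DataFrame):
        df = scores
    else:
        df = pd.DataFrame(scores)
    if df.isna().any().any():
        raise ValueError("score table has missing entries")
    if df.shape[0] < 5:
        raise ValueError("need >= 5 paired observations per model pair")
    pairs = list(combinations(df.columns, 2))
    raw = []
    for a, b in pairs:
        diff = df[a].to_numpy() - df[b].to_numpy()
        if np.allclose(diff, 0):
            raw.append(1.0)
        else:
            raw.append(float(stats.wilcoxon(df[a], df[b], alternative=alternative,
                                            zero_method="wilcox").pvalue))
    if pairs:
        _, adj, _, _ = multipletests(raw, method="holm-sidak")
    else:
        adj = []
    return pd.DataFrame({"model_a": [a for a, _ in pairs],
                         "model_b": [b for _, b in pairs],
                         "p_raw": raw, "p_adjusted": adj,
                         "significant": [p < 0.05 for p in adj]})


def holm_sidak_adjust(pvalues):
    """Step-down Holm-Sidak adjustment: for p sorted ascending,
    p_adj_(i) = max_{j<=i} 1 - (1 - p_(j))^(m-j+1), clipped to 1."""
    p = np.asarray(pvalues, dtype=np.float64)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(running, 1.0)
    return adj
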