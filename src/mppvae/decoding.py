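"""Decoding covariates from unsorted spikes alone.

Given a trained state-space model, decoding computes the posterior over
the hidden state path from the per-bin mark sets only, then pushes state
samples through the observation decoder to obtain the posterior over the
covariate.  The state posterior is approximated by Laplace: the MAP path
is found by Newton iterations on a *concavified* objective — the
per-bin Renyi/chi bound is not concave in general, so its inner smooth
maps are linearized at the current iterate (the Gauss-Newton composite
technique), which makes every per-bin term globally concave, guarantees
ascent directions, and yields a positive-definite Laplace precision.

The concave composites and their derivatives are analytic: the latent
samples inside each bound term are frozen at the expansion point, and
the state enters only through Gaussian quadratic forms, so no network
differentiation is needed on the decoding path.  All Hessian solves use
the block-tridiagonal structure (cost linear in the number of bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import block_tridiag as bt
from .core_data import BinnedDataset
from .nets import LOG2PI


# ---------------------------------------------------------------------------
# concave per-bin terms (frozen latent samples, analytic derivatives)
# ---------------------------------------------------------------------------

class RenyiSpikeTerm:
    """pi(F(x)) = (1/alpha) log( (1/L) sum_l F_l ), F_l = w_l^alpha > 0,
    linearized in x at the expansion point.

    Stored in a shifted representation (log-domain anchor) for numerical
    stability; the outer log keeps the composite concave since its
    argument is affine in x after linearization.
    """

    def __init__(self, alpha, log_w0, grad_log_w, x_bar, dec_mean=None, dec_prec=None):
        # log_w0: (L,) log-weights at x_bar; grad_log_w: (L, d)
        self.alpha = alpha
        self.x_bar = np.asarray(x_bar, dtype=np.float64)
        self.log_w0 = np.asarray(log_w0, dtype=np.float64)
        a = alpha * self.log_w0
        self.shift = np.max(a) if np.any(np.isfinite(a)) else 0.0
        self.F0 = np.exp(a - self.shift)                    # (L,)
        self.J = alpha * self.F0[:, None] * np.asarray(grad_log_w)   # (L, d)
        self.dec_mean, self.dec_prec = dec_mean, dec_prec   # (L, d) each

    def _s(self, x):
        return np.mean(self.F0 + self.J @ (x - self.x_bar))

    def value(self, x):
        s = self._s(x)
        if s <= 0:
            return -np.inf
        return (np.log(s) + self.shift) / self.alpha

    def _exact_log_w(self, x):
        q0 = np.sum(self.dec_prec * (self.x_bar - self.dec_mean) ** 2, axis=-1)
        qx = np.sum(self.dec_prec * (x - self.dec_mean) ** 2, axis=-1)
        return self.log_w0 + 0.5 * (q0 - qx)

    def exact_value(self, x):
        """The frozen-sample (unlinearized) bound at x: the latent samples
        and encoder arguments stay at the expansion point, so the state
        enters only through the decoder's Gaussian quadratic."""
        if self.dec_mean is None:
            return self.value(x)
        lw = self.alpha * self._exact_log_w(x)
        return (ad.logsumexp(lw, axis=-1) - np.log(len(lw))) / self.alpha

    def grad(self, x):
        s = self._s(x)
        return self.J.mean(axis=0) / (self.alpha * s)

    def hess(self, x):
        s = self._s(x)
        g = self.J.mean(axis=0)
        return -np.outer(g, g) / (self.alpha * s * s)


class ChiStateTerm:
    """rho(G(x)) = -((1/L) sum_l exp(beta G_l))^(1/beta) with G_l the
    log-weights (including log lambda0 and the bin width), linearized at
    the expansion point; -exp of a convex log-sum-exp is concave."""

    def __init__(self, beta, log_w0, grad_log_w, x_bar, dec_mean=None, dec_prec=None):
        self.beta = beta
        self.x_bar = np.asarray(x_bar, dtype=np.float64)
        self.G0 = np.asarray(log_w0, dtype=np.float64)      # (L,)
        self.J = np.asarray(grad_log_w)                     # (L, d)
        self.dec_mean, self.dec_prec = dec_mean, dec_prec

    def exact_value(self, x):
        if self.dec_mean is None:
            return self.value(x)
        q0 = np.sum(self.dec_prec * (self.x_bar - self.dec_mean) ** 2, axis=-1)
        qx = np.sum(self.dec_prec * (x - self.dec_mean) ** 2, axis=-1)
        g = self.G0 + 0.5 * (q0 - qx)
        m = (ad.logsumexp(self.beta * g, axis=-1) - np.log(len(g))) / self.beta
        return -np.exp(min(m, 50.0))

    def _parts(self, x):
        g = self.G0 + self.J @ (x - self.x_bar)
        b = self.beta
        L = len(g)
        m = (ad.logsumexp(b * g, axis=-1) - np.log(L)) / b
        p = np.exp(b * g - ad.logsumexp(b * g, axis=-1))
        return g, m, p

    def value(self, x):
        _, m, _ = self._parts(x)
        return -np.exp(min(m, 50.0))

    def grad(self, x):
        _, m, p = self._parts(x)
        gvec = p @ self.J
        return -np.exp(min(m, 50.0)) * gvec

    def hess(self, x):
        _, m, p = self._parts(x)
        gvec = p @ self.J
        second = self.beta * ((self.J.T * p) @ self.J - np.outer(gvec, gvec))
        return -np.exp(min(m, 50.0)) * (np.outer(gvec, gvec) + second)


@dataclass
class LaplaceResult:
    mean: np.ndarray                     # (R, d) MAP path
    precision: bt.BlockTridiagonalSPD    # negative Hessian at the mode
    iterations: int
    converged: bool
    objective_trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# chain prior in information form (numpy)
# ---------------------------------------------------------------------------

def chain_info_form(a1, V1, F, a, V, R):
    """Block-tridiagonal precision + information vector + log normalizer of
    the linear-Gaussian chain prior."""
    d = len(a1)
    D = np.zeros((R, d, d))
    O = np.zeros((max(R - 1, 0), d, d))
    h = np.zeros((R, d))
    D[0] += V1
    h[0] += V1 @ a1
    for r in range(R - 1):
        D[r + 1] += V
        D[r] += F.T @ V @ F
        O[r] = -F.T @ V
        h[r + 1] += V @ a
        h[r] += -F.T @ V @ a
    s1, ld1 = np.linalg.slogdet(V1)
    s, ld = np.linalg.slogdet(V)
    log_norm = 0.5 * (ld1 + (R - 1) * ld) - 0.5 * R * d * LOG2PI
    return bt.BlockTridiagonalSPD(D, O), h, log_norm


def _chain_logpdf(x, P: bt.BlockTridiagonalSPD, h, log_norm, quad_const):
    """log p(x) = log_norm - 0.5 (x-mu)' P (x-mu) in information form:
    = log_norm + h'x - 0.5 x'Px - 0.5 mu'Pmu  (quad_const = 0.5 mu'Pmu)."""
    Px = _bt_matvec(P, x)
    return log_norm + float(np.sum(h * x)) - 0.5 * float(np.sum(x * Px)) - quad_const


def _bt_matvec(P: bt.BlockTridiagonalSPD, x):
    D, O = ad.value_of(P.diag), ad.value_of(P.offdiag)
    R = P.R
    out = np.einsum("rij,rj->ri", D, x)
    if R > 1:
        out[:-1] += np.einsum("rij,rj->ri", O, x[1:])
        out[1:] += np.einsum("rji,rj->ri", O, x[:-1])
    return out


# ---------------------------------------------------------------------------
# term providers
# ---------------------------------------------------------------------------

class GaussianSurrogateProvider:
    """Per-bin quadratic (linear-Gaussian) terms: value = log N(m_r | x_r, J_r^-1).

    The exactness oracle: with these terms the objective is quadratic and
    Newton must recover the closed-form Gaussian posterior.
    """

    def __init__(self, means, precisions):
        self.means = np.asarray(means, dtype=np.float64)
        self.precisions = np.asarray(precisions, dtype=np.float64)

    def expand(self, x_bar, rng):
        terms = []
        for r in range(len(self.means)):
            m, J = self.means[r], self.precisions[r]
            terms.append([_QuadTerm(m, J)])
        return terms


class _QuadTerm:
    def __init__(self, m, J):
        self.m, self.J = m, J
        s, ld = np.linalg.slogdet(J)
        self._norm = 0.5 * ld - 0.5 * len(m) * LOG2PI

    def value(self, x):
        r = x - self.m
        return self._norm - 0.5 * float(r @ self.J @ r)

    exact_value = value

    def grad(self, x):
        return -self.J @ (x - self.m)

    def hess(self, x):
        return -self.J


class JMIBinTermProvider:
    """Per-bin Renyi/chi bound terms from the trained joint mark intensity.

    Latent samples are drawn from the jmi encoders at the expansion point
    and frozen; a fixed base-noise stream (common random numbers across
    re-expansions) keeps successive linearizations coherent.
    """

    def __init__(self, jmi, data: BinnedDataset, alpha=None, beta=None,
                 L_dec=32, absorb_dt=False, seed=0):
        self.jmi = jmi
        self.data = data
        cfg = jmi.bound_cfg
        self.alpha = alpha if alpha is not None else cfg.alpha
        self.beta = beta if beta is not None else cfg.beta
        self.L = int(L_dec)
        self.log_dt = 0.0 if absorb_dt else float(np.log(data.dt_bin))
        rng = np.random.default_rng(seed)
        R = data.R
        self._eps_state = rng.standard_normal((R, self.L, jmi.d_z))
        self._eps_spike = [rng.standard_normal((n, self.L, jmi.d_z)) if n else None
                           for n in data.counts]

    def expand(self, x_bar, rng):
        jmi, data = self.jmi, self.data
        R = data.R
        ll0 = float(jmi.log_lambda0.value)
        terms = [[] for _ in range(R)]
        # state-side (chi) terms, batched over bins
        em, ep = jmi.encoder_x.forward_np(x_bar)                     # (R, d_z)
        z = em[:, None, :] + self._eps_state / np.sqrt(ep[:, None, :])   # (R, L, d_z)
        log_q = _diag_logpdf_np(z, em[:, None, :], ep[:, None, :])
        zf = z.reshape(R * self.L, -1)
        dm, dp = jmi.decoder_x.forward_np(zf)
        dm = dm.reshape(R, self.L, -1)
        dp = dp.reshape(R, self.L, -1)
        log_px = _diag_logpdf_np(x_bar[:, None, :], dm, dp)
        log_pz = -0.5 * np.sum(z * z, axis=-1) - 0.5 * jmi.d_z * LOG2PI
        log_w = ll0 + self.log_dt + log_px + log_pz - log_q          # (R, L)
        grads = dp * (dm - x_bar[:, None, :])                        # d log p(x|z) / dx
        for r in range(R):
            terms[r].append(ChiStateTerm(self.beta, log_w[r], grads[r], x_bar[r],
                                         dec_mean=dm[r], dec_prec=dp[r]))
        # spike-side (Renyi) terms
        for r in range(R):
            n_r = data.counts[r]
            if not n_r:
                continue
            ks = np.asarray(data.mark_sets[r], dtype=np.float64)
            xb = np.broadcast_to(x_bar[r], (n_r, len(x_bar[r])))
            em_s, ep_s = jmi.encoder_xk.forward_np(np.concatenate([xb, ks], axis=1))
            zs = em_s[:, None, :] + self._eps_spike[r] / np.sqrt(ep_s[:, None, :])
            log_qs = _diag_logpdf_np(zs, em_s[:, None, :], ep_s[:, None, :])
            zsf = zs.reshape(n_r * self.L, -1)
            dxm, dxp = jmi.decoder_x.forward_np(zsf)
            dkm, dkp = jmi.decoder_k.forward_np(zsf)
            dxm = dxm.reshape(n_r, self.L, -1)
            dxp = dxp.reshape(n_r, self.L, -1)
            log_px_s = _diag_logpdf_np(x_bar[r][None, None, :], dxm, dxp)
            log_pk = _diag_logpdf_np(ks[:, None, :], dkm.reshape(n_r, self.L, -1),
                                     dkp.reshape(n_r, self.L, -1))
            log_pz_s = -0.5 * np.sum(zs * zs, axis=-1) - 0.5 * jmi.d_z * LOG2PI
            log_ws = ll0 + log_px_s + log_pk + log_pz_s - log_qs     # (n_r, L)
            grad_s = dxp * (dxm - x_bar[r][None, None, :])           # (n_r, L, d)
            for i in range(n_r):
                terms[r].append(RenyiSpikeTerm(self.alpha, log_ws[i], grad_s[i], x_bar[r],
                                               dec_mean=dxm[i], dec_prec=dxp[i]))
        return terms


def _diag_logpdf_np(u, mean, prec):
    resid = u - mean
    return 0.5 * (np.sum(np.log(prec), axis=-1) - np.sum(prec * resid * resid, axis=-1)) \
        - 0.5 * u.shape[-1] * LOG2PI


def concave_bin_bound(provider, x_bar, rng=None):
    """Expand the concavified per-bin bounds at `x_bar` (R, d).

    Returns the list of per-bin concave terms; each matches the
    unapproximated bound in value and gradient at the expansion point and
    has a negative-semidefinite Hessian everywhere.
    """
    return provider.expand(np.asarray(x_bar, dtype=np.float64),
                           rng or np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Newton MAP + Laplace
# ---------------------------------------------------------------------------

def newton_map(dyn_matrices, provider, R, init=None, K_max=50, tol=1e-6,
               seed=0, max_halvings=10):
    """MAP of log p(x) + sum_r L_r(x_r) by concavified Newton ascent.

    ``dyn_matrices`` is (a1, V1, F, a, V) with V1, V precisions.  Each
    iteration re-expands the concave approximation at the current
    iterate, solves the block-tridiagonal Newton system, and backtracks
    (step halving) if the approximated objective decreases.
    """
    a1, V1, F, a, V = (np.asarray(m, dtype=np.float64) for m in dyn_matrices)
    d = len(a1)
    P_p, h_p, log_norm = chain_info_form(a1, V1, F, a, V, R)
    mu_p = bt.solve(P_p, h_p)
    quad_const = 0.5 * float(np.sum(mu_p * _bt_matvec(P_p, mu_p)))
    if init is None:
        x = np.empty((R, d))
        x[0] = a1
        for r in range(1, R):
            x[r] = F @ x[r - 1] + a
    else:
        x = np.array(init, dtype=np.float64)
    rng = np.random.default_rng(seed)

    def objective(xp, tp):
        return _chain_logpdf(xp, P_p, h_p, log_norm, quad_const) + _terms_exact(tp, xp)

    trace = []
    converged = False
    updates = 0
    terms = provider.expand(x, rng)
    f_x = objective(x, terms)
    for _ in range(K_max):
        trace.append(f_x)
        grad = h_p - _bt_matvec(P_p, x)
        neg_hess = ad.value_of(P_p.diag).copy()
        for r in range(R):
            for t in terms[r]:
                grad[r] += t.grad(x[r])
                neg_hess[r] -= t.hess(x[r])
        Lambda = bt.BlockTridiagonalSPD(neg_hess, ad.value_of(P_p.offdiag))
        try:
            step = bt.solve(Lambda, grad)
        except bt.DecompositionError:
            return LaplaceResult(x, Lambda, updates, False, trace)
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        # backtracking: the concavified surrogate supplies the ascent
        # direction; acceptance is judged on the re-expanded objective,
        # which guards the Monte-Carlo re-linearization noise
        scale, improved = 1.0, False
        for _ in range(max_halvings + 1):
            cand = x + scale * step
            terms_c = provider.expand(cand, rng)
            f_c = objective(cand, terms_c)
            if f_c >= f_x - 1e-12:
                improved = True
                break
            scale *= 0.5
        if not improved:
            converged = True   # no ascent at line-search resolution
            break
        x, terms, f_x = cand, terms_c, f_c
        updates += 1
    trace.append(f_x)
    it = updates
    # Laplace precision: negative Hessian of the final expansion at the mode
    neg_hess = ad.value_of(P_p.diag).copy()
    for r in range(R):
        for t in terms[r]:
            neg_hess[r] -= t.hess(x[r])
    Lambda = bt.BlockTridiagonalSPD(neg_hess, ad.value_of(P_p.offdiag))
    try:
        bt.factorize(Lambda)
    except bt.DecompositionError:
        converged = False
    return LaplaceResult(x, Lambda, it, converged, trace)


def _terms_value(terms, x):
    return sum(t.value(x[r]) for r in range(len(terms)) for t in terms[r])


def _terms_exact(terms, x):
    return sum(t.exact_value(x[r]) for r in range(len(terms)) for t in terms[r])


# ---------------------------------------------------------------------------
# covariate posterior + metric
# ---------------------------------------------------------------------------

def decode_covariate(model, laplace: LaplaceResult, S: int, seed=0):
    """Posterior over y by decoder averaging over Laplace state samples.

    Returns (y_mean (R, D_y), y_var (R, D_y)); the variance combines the
    decoder noise and the spread of decoded means (law of total
    variance, diagonal).  Deterministic given the seed.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    post = bt.PosteriorGaussian(laplace.mean, laplace.precision)
    xs = post.sample(S, seed)                           # (S, R, d)
    R = xs.shape[1]
    means = np.empty((S, R, model.d_y))
    varis = np.empty((S, R, model.d_y))
    for s in range(S):
        m, p = model.obs_y.forward_np(xs[s])
        means[s] = m
        varis[s] = 1.0 / p
    y_mean = means.mean(axis=0)
    y_var = varis.mean(axis=0) + means.var(axis=0)
    return y_mean, y_var


def decode_mse(y_hat, y_true) -> float:
    """(1/R) sum_r || y_hat_r - y_r ||^2."""
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=np.float64))
    y_true = np.atleast_2d(np.asarray(y_true, dtype=np.float64))
    if y_hat.shape != y_true.shape:
        raise ValueError(f"shape mismatch {y_hat.shape} vs {y_true.shape}")
    return float(np.mean(np.sum((y_hat - y_true) ** 2, axis=1)))
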