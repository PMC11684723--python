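"""Gaussian networks and optimization utilities.

A :class:`GaussianNet` maps an input vector to the mean and the diagonal
precision of a Gaussian: the building block for the decoders
``p(x|z)``, ``p(kappa|z)``, the observation model ``p(y|x)`` and every
encoder in the package.  Precisions are diagonal with softplus-transformed
entries plus a fixed floor, which keeps them positive definite for every
input and keeps the chi-term densities cheap.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

LOG2PI = float(np.log(2.0 * np.pi))
PRECISION_FLOOR = 1e-4


def diag_gaussian_logpdf(u, mean, prec_diag):
    """log N(u | mean, diag(prec)^-1), summed over the last axis.

    Works on plain arrays or autodiff tensors (broadcasting allowed).
    """
    d = ad.value_of(u).shape[-1] if ad.value_of(u).ndim else 1
    resid = ad.add(u, ad.mul(mean, -1.0)) if isinstance(u, ad.Tensor) or isinstance(mean, ad.Tensor) else u - mean
    if isinstance(resid, ad.Tensor) or isinstance(prec_diag, ad.Tensor):
        quad = ad.tsum(ad.mul(prec_diag, ad.mul(resid, resid)), axis=-1)
        logdet = ad.tsum(ad.log(prec_diag), axis=-1)
        return ad.add(ad.mul(ad.add(logdet, ad.mul(quad, -1.0)), 0.5), -0.5 * d * LOG2PI)
    quad = np.sum(prec_diag * resid * resid, axis=-1)
    logdet = np.sum(np.log(prec_diag), axis=-1)
    return 0.5 * (logdet - quad) - 0.5 * d * LOG2PI


def std_normal_logpdf(z):
    zz = ad.value_of(z)
    d = zz.shape[-1]
    if isinstance(z, ad.Tensor):
        return ad.add(ad.mul(ad.tsum(ad.mul(z, z), axis=-1), -0.5), -0.5 * d * LOG2PI)
    return -0.5 * np.sum(zz * zz, axis=-1) - 0.5 * d * LOG2PI


class GaussianNet:
    """MLP from an input vector to (mean, diagonal precision).

    Parameters
    ----------
    in_dim, out_dim : int
        Input and output dimensions.
    hidden : sequence of int
        Hidden-layer widths; empty for an affine map.
    rng : numpy Generator
        Source for the (deterministic, seeded) initialization.
    const_precision : bool
        If True the precision does not depend on the input (a free
        parameter vector); used for affine/linear-Gaussian instances.
    """

    def __init__(self, in_dim, out_dim, hidden=(64, 64), rng=None, const_precision=False,
                 prec_cap=None):
        if in_dim < 1 or out_dim < 1:
            raise ValueError("dimensions must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.out_dim = int(in_dim), int(out_dim)
        self.hidden = tuple(int(h) for h in hidden)
        self.const_precision = bool(const_precision)
        self.prec_cap = prec_cap
        self.weights = []   # hidden stack
        self.biases = []
        prev = in_dim
        for h in self.hidden:
            s = np.sqrt(2.0 / (prev + h))
            self.weights.append(ad.parameter(rng.normal(0.0, s, (prev, h))))
            self.biases.append(ad.parameter(np.zeros(h)))
            prev = h
        s = np.sqrt(2.0 / (prev + out_dim))
        self.w_mean = ad.parameter(rng.normal(0.0, s, (prev, out_dim)))
        self.b_mean = ad.parameter(np.zeros(out_dim))
        if const_precision:
            self.b_prec = ad.parameter(np.zeros(out_dim))  # softplus(0) ~ 0.69
            self.w_prec = None
        else:
            self.w_prec = ad.parameter(rng.normal(0.0, 0.1 * s, (prev, out_dim)))
            self.b_prec = ad.parameter(np.zeros(out_dim))

    # ------------------------------------------------------------------
    def parameters(self):
        ps = list(self.weights) + list(self.biases) + [self.w_mean, self.b_mean, self.b_prec]
        if self.w_prec is not None:
            ps.append(self.w_prec)
        return ps

    def __call__(self, x):
        """Forward pass; returns (mean, prec_diag) as autodiff tensors.

        `x` has shape (..., in_dim) (any number of batch axes).
        """
        h = ad.as_tensor(x)
        for w, b in zip(self.weights, self.biases):
            h = ad.tanh(ad.add(ad.matmul(h, w), b))
        mean = ad.add(ad.matmul(h, self.w_mean), self.b_mean)
        if self.const_precision:
            raw = ad.add(ad.mul(mean, 0.0), self.b_prec)  # broadcast to batch shape
        else:
            raw = ad.add(ad.matmul(h, self.w_prec), self.b_prec)
        prec = ad.add(ad.softplus(raw), PRECISION_FLOOR)
        if self.prec_cap is not None:
            # soft cap: bounds how sharply a density can concentrate
            prec = ad.mul(ad.tanh(ad.mul(prec, 1.0 / self.prec_cap)), self.prec_cap)
        return mean, prec

    def forward_np(self, x):
        """Numpy-only forward pass (no tape)."""
        mean, prec = self(np.asarray(x, dtype=np.float64))
        return mean.value, prec.value

    # checkpointing ----------------------------------------------------
    def state_dict(self):
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, d):
        for i, p in enumerate(self.parameters()):
            p.value = np.asarray(d[f"p{i}"], dtype=np.float64).reshape(p.value.shape)


def sample_diag_gaussian(mean, prec_diag, eps):
    """Reparameterized draw mean + eps / sqrt(prec)."""
    if isinstance(mean, ad.Tensor) or isinstance(prec_diag, ad.Tensor):
        return ad.add(mean, ad.mul(eps, ad.power(ad.as_tensor(prec_diag), -0.5)))
    return mean + eps / np.sqrt(prec_diag)


def make_affine_gaussian_net(A, c, prec_diag):
    """Exact affine Gaussian net: mean = x A + c, constant diag precision.

    The workhorse for linear-Gaussian oracle fixtures.
    """
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    c = np.asarray(c, dtype=np.float64)
    prec_diag = np.asarray(prec_diag, dtype=np.float64)
    net = GaussianNet(A.shape[0], A.shape[1], hidden=(), const_precision=True)
    net.w_mean.value = A.copy()
    net.b_mean.value = c.copy()
    # invert softplus so softplus(b_prec) + floor == prec_diag
    target = np.maximum(prec_diag - PRECISION_FLOOR, 1e-12)
    net.b_prec.value = np.where(target > 30, target, np.log(np.expm1(np.minimum(target, 30.0))))
    return net


class Adam:
    """Adam on a list of parameter tensors (maximization via negated grads
    is the caller's choice; this implements plain gradient *descent*)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, maximize=False):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = -p.grad if maximize else p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def collect_state(objs: dict) -> dict:
    """Flatten {name: GaussianNet|Tensor} into one array dict (checkpoints)."""
    out = {}
    for name, obj in objs.items():
        if isinstance(obj, GaussianNet):
            for k, v in obj.state_dict().items():
                out[f"{name}.{k}"] = v
        else:
            out[name] = ad.value_of(obj).copy()
    return out


def load_state(objs: dict, state: dict):
    for name, obj in objs.items():
        if isinstance(obj, GaussianNet):
            sub = {k[len(name) + 1:]: v for k, v in state.items() if k.startswith(name + ".")}
            obj.load_state_dict(sub)
        else:
            obj.value = np.asarray(state[name], dtype=np.float64).reshape(obj.value.shape)
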