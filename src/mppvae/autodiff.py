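"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objectives in this package (Renyi/chi point-process bounds,
the state-space ELBO) are maximized with stochastic gradient ascent over
Gaussian-network parameters, and their gradients flow through a
block-Cholesky factorization of the structured posterior precision.  This
module provides the small set of differentiable primitives needed for
that: broadcast-aware arithmetic, matmul, log-sum-exp, gather/scatter,
Cholesky and triangular solves.

Only what the package uses is implemented; the engine is a plain tape
(each :class:`Tensor` remembers its parents and a backward closure) and
all values are float64 numpy arrays.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular as _solve_tri


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("value", "grad", "parents", "bwd", "requires_grad")

    def __init__(self, value, requires_grad=False, parents=(), bwd=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------------
    def backward(self, seed=None):
        """Accumulate gradients of `self` into every upstream tensor."""
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if id(node) in seen:
                continue
            if done:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node.parents:
                    if id(p) not in seen and p.requires_grad:
                        stack.append((p, False))
        self.grad = np.ones_like(self.value) if seed is None else np.asarray(seed, dtype=np.float64)
        for node in reversed(topo):
            if node.bwd is not None and node.grad is not None:
                node.bwd(node.grad)
            # free intermediate grads? keep them; tapes are short-lived

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.value.shape)
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    @property
    def mT(self):
        return swap_last(self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(x) -> Tensor:
    """A leaf tensor that collects gradients."""
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def value_of(x):
    """Plain numpy value of a Tensor or array-like (pass-through)."""
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


# ---------------------------------------------------------------------------
# elementwise / arithmetic primitives
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.value + b.value, parents=(a, b))
    if out.requires_grad:
        def bwd(g):
            if a.requires_grad:
                a._accum(g)
            if b.requires_grad:
                b._accum(g)
        out.bwd = bwd
    return out


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.value * b.value, parents=(a, b))
    if out.requires_grad:
        def bwd(g):
            if a.requires_grad:
                a._accum(g * b.value)
            if b.requires_grad:
                b._accum(g * a.value)
        out.bwd = bwd
    return out


def power(a, p: float):
    a = as_tensor(a)
    out = Tensor(a.value ** p, parents=(a,))
    if out.requires_grad:
        def bwd(g):
            a._accum(g * p * a.value ** (p - 1.0))
        out.bwd = bwd
    return out


def exp(a):
    if not isinstance(a, Tensor):
        return np.exp(a)
    out = Tensor(np.exp(a.value), parents=(a,))
    if out.requires_grad:
        def bwd(g):
            a._accum(g * out.value)
        out.bwd = bwd
    return out


def log(a):
    if not isinstance(a, Tensor):
        return np.log(a)
    out = Tensor(np.log(a.value), parents=(a,))
    if out.requires_grad:
        def bwd(g):
            a._accum(g / a.value)
        out.bwd = bwd
    return out


def sqrt(a):
    if not isinstance(a, Tensor):
        return np.sqrt(a)
    return power(a, 0.5)


def tanh(a):
    if not isinstance(a, Tensor):
        return np.tanh(a)
    out = Tensor(np.tanh(a.value), parents=(a,))
    if out.requires_grad:
        def bwd(g):
            a._accum(g * (1.0 - out.value ** 2))
        out.bwd = bwd
    return out


def _softplus_np(x):
    return np.logaddexp(0.0, x)


def softplus(a):
    if not isinstance(a, Tensor):
        return _softplus_np(a)
    out = Tensor(_softplus_np(a.value), parents=(a,))
    if out.requires_grad:
        def bwd(g):
            a._accum(g / (1.0 + np.exp(-a.value)))
        out.bwd = bwd
    return out


def minimum_const(a, cap: float):
    """Elementwise min(a, cap); gradient is zero where the cap binds."""
    if not isinstance(a, Tensor):
        return np.minimum(a, cap)
    mask = a.value <= cap
    out = Tensor(np.where(mask, a.value, cap), parents=(a,))
    if out.requires_grad:
        def bwd(g):
            a._accum(g * mask)
        out.bwd = bwd
    return out


def stop_gradient(a):
    """Detach a tensor from the tape (identity value, no gradient)."""
    return Tensor(value_of(a))


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    if not isinstance(a, Tensor):
        return np.sum(a, axis=axis, keepdims=keepdims)
    out = Tensor(a.value.sum(axis=axis, keepdims=keepdims), parents=(a,))
    if out.requires_grad:
        def bwd(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.value.shape))
        out.bwd = bwd
    return out


def tmean(a, axis=None, keepdims=False):
    if not isinstance(a, Tensor):
        return np.mean(a, axis=axis, keepdims=keepdims)
    n = a.value.size if axis is None else a.value.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def logsumexp(a, axis=-1, keepdims=False):
    """Numerically stable log(sum(exp(a))) along `axis`."""
    if not isinstance(a, Tensor):
        from scipy.special import logsumexp as _lse
        return _lse(a, axis=axis, keepdims=keepdims)
    x = a.value
    xmax = np.max(x, axis=axis, keepdims=True)
    xmax = np.where(np.isfinite(xmax), xmax, 0.0)
    es = np.exp(x - xmax)
    s = es.sum(axis=axis, keepdims=True)
    val = np.log(s) + xmax
    if not keepdims:
        val = np.squeeze(val, axis=axis)
    out = Tensor(val, parents=(a,))
    if out.requires_grad:
        soft = es / s
        def bwd(g):
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(gg * soft)
        out.bwd = bwd
    return out


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------

def reshape(a, shape):
    a = as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    out = Tensor(a.value.reshape(shape), parents=(a,))
    if out.requires_grad:
        def bwd(g):
            a._accum(np.asarray(g).reshape(a.value.shape))
        out.bwd = bwd
    return out


def swap_last(a):
    """Transpose the last two axes."""
    a = as_tensor(a)
    out = Tensor(np.swapaxes(a.value, -1, -2), parents=(a,))
    if out.requires_grad:
        def bwd(g):
            a._accum(np.swapaxes(np.asarray(g), -1, -2))
        out.bwd = bwd
    return out


def concatenate(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.value.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bwd(g):
            parts = np.split(np.asarray(g), splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)
        out.bwd = bwd
    return out


def stack(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.value for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        def bwd(g):
            parts = np.moveaxis(np.asarray(g), axis, 0)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)
        out.bwd = bwd
    return out


def take(a, idx):
    """Indexing / gather; `idx` may be any numpy-style index."""
    a = as_tensor(a)
    out = Tensor(a.value[idx], parents=(a,))
    if out.requires_grad:
        def bwd(g):
            buf = np.zeros_like(a.value)
            np.add.at(buf, idx, np.asarray(g))
            a._accum(buf)
        out.bwd = bwd
    return out


def index_add(n: int, idx, src, tail_shape=()):
    """Scatter-add rows of `src` into a zero tensor of shape (n, *tail_shape)."""
    src = as_tensor(src)
    buf = np.zeros((n,) + tuple(tail_shape), dtype=np.float64)
    np.add.at(buf, idx, src.value)
    out = Tensor(buf, parents=(src,))
    if out.requires_grad:
        def bwd(g):
            src._accum(np.asarray(g)[idx])
        out.bwd = bwd
    return out


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.value @ b.value, parents=(a, b))
    if out.requires_grad:
        def bwd(g):
            g = np.asarray(g)
            if a.requires_grad:
                if b.value.ndim == 1:
                    ga = np.multiply.outer(g, b.value) if a.value.ndim > 1 else np.outer(g, b.value)
                    if a.value.ndim == 1:
                        ga = g * b.value  # scalar output case not used
                    a._accum(_unbroadcast(ga, a.value.shape))
                else:
                    if a.value.ndim == 1:
                        a._accum(_unbroadcast(g @ np.swapaxes(b.value, -1, -2), a.value.shape))
                    else:
                        a._accum(_unbroadcast(g @ np.swapaxes(b.value, -1, -2), a.value.shape))
            if b.requires_grad:
                if a.value.ndim == 1:
                    gb = np.outer(a.value, g) if b.value.ndim > 1 else g * a.value
                    b._accum(_unbroadcast(gb, b.value.shape))
                elif b.value.ndim == 1:
                    gb = np.swapaxes(a.value, -1, -2) @ np.expand_dims(g, -1)
                    b._accum(_unbroadcast(gb[..., 0], b.value.shape))
                else:
                    b._accum(_unbroadcast(np.swapaxes(a.value, -1, -2) @ g, b.value.shape))
        out.bwd = bwd
    return out


def _phi(m):
    """Lower triangle with halved diagonal (Cholesky adjoint helper)."""
    out = np.tril(m)
    out[np.diag_indices_from(out)] *= 0.5
    return out


def cholesky(a):
    """Lower Cholesky factor of an SPD matrix (2-D only)."""
    a = as_tensor(a)
    L = np.linalg.cholesky(a.value)
    out = Tensor(L, parents=(a,))
    if out.requires_grad:
        def bwd(g):
            # Murray (2016): abar = Linv^T phi(L^T g) Linv, symmetrized
            P = _phi(L.T @ np.asarray(g))
            S = _solve_tri(L, P.T, lower=True, trans="T")
            abar = _solve_tri(L, S.T, lower=True, trans="T").T
            a._accum(0.5 * (abar + abar.T))
        out.bwd = bwd
    return out


def solve_triangular(L, b, lower=True, trans=False):
    """Solve L x = b (or L^T x = b when trans) for triangular 2-D L."""
    L, b = as_tensor(L), as_tensor(b)
    b2 = b.value if b.value.ndim > 1 else b.value[:, None]
    x = _solve_tri(L.value, b2, lower=lower, trans="T" if trans else "N")
    xv = x if b.value.ndim > 1 else x[:, 0]
    out = Tensor(xv, parents=(L, b))
    if out.requires_grad:
        def bwd(g):
            g2 = np.asarray(g)
            g2 = g2 if g2.ndim > 1 else g2[:, None]
            # gbar solves the transposed system
            gb = _solve_tri(L.value, g2, lower=lower, trans="N" if trans else "T")
            if b.requires_grad:
                b._accum(gb if b.value.ndim > 1 else gb[:, 0])
            if L.requires_grad:
                if trans:
                    gL = -x @ gb.T
                else:
                    gL = -gb @ x.T
                mask = np.tril(np.ones_like(L.value)) if lower else np.triu(np.ones_like(L.value))
                L._accum(gL * mask)
        out.bwd = bwd
    return out


# ---------------------------------------------------------------------------
# gradient utilities
# ---------------------------------------------------------------------------

def grad_check(f, xs, eps=1e-6, seed=None):
    """Max relative error between tape gradients of scalar f(*xs) and central
    finite differences.  `xs` are numpy arrays; used by the test-suite."""
    params = [parameter(x) for x in xs]
    out = f(*params)
    out.backward()
    worst = 0.0
    for p in params:
        g_num = np.zeros_like(p.value)
        flat = p.value.reshape(-1)
        gn = g_num.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            fp = value_of(f(*params))
            flat[i] = orig - eps
            fm = value_of(f(*params))
            flat[i] = orig
            gn[i] = (fp - fm) / (2 * eps)
        denom = max(1.0, np.abs(g_num).max(), np.abs(p.grad).max())
        worst = max(worst, np.abs(p.grad - g_num).max() / denom)
    return worst
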