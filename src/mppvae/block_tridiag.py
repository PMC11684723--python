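"""Gaussian linear algebra for block-tridiagonal precision matrices.

The structured variational posterior over a latent state path, and the
Laplace approximation produced by MAP decoding, are Gaussians whose
precision couples only temporally adjacent d-dimensional state blocks.
A block Cholesky factorization (forward recursion over bins) gives
solves, log-determinants, and sampling at cost linear in the number of
bins R; no dense (R d) x (R d) matrix is ever formed on these paths.

All routines run on plain numpy arrays or autodiff tensors, so the ELBO
can differentiate through posterior sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad


class DecompositionError(np.linalg.LinAlgError):
    """Cholesky failure; carries the index of the failing block."""

    def __init__(self, block_index: int):
        self.block_index = block_index
        super().__init__(f"block {block_index} is not positive definite")


@dataclass
class BlockTridiagonalSPD:
    """Symmetric positive-definite matrix with R diagonal blocks (d x d)
    and R-1 upper off-diagonal blocks coupling bin r to r+1 (the lower
    couplings are their transposes)."""

    diag: object      # (R, d, d) array or Tensor
    offdiag: object   # (R-1, d, d) array or Tensor; empty for R = 1

    def __post_init__(self):
        dv = ad.value_of(self.diag)
        asym = np.max(np.abs(dv - np.swapaxes(dv, -1, -2))) if dv.size else 0.0
        if asym > 1e-8:
            warnings.warn(f"diagonal blocks symmetrized (asymmetry {asym:.2e})")
        sym = ad.mul(ad.add(self.diag, ad.swap_last(ad.as_tensor(self.diag))), 0.5)
        self.diag = sym if isinstance(self.diag, ad.Tensor) else sym.value

    @property
    def R(self) -> int:
        return ad.value_of(self.diag).shape[0]

    @property
    def d(self) -> int:
        return ad.value_of(self.diag).shape[-1]

    def to_dense(self) -> np.ndarray:
        """Dense assembly — for small-instance oracles and tests only."""
        R, d = self.R, self.d
        D = ad.value_of(self.diag)
        O = ad.value_of(self.offdiag)
        out = np.zeros((R * d, R * d))
        for r in range(R):
            out[r * d:(r + 1) * d, r * d:(r + 1) * d] = D[r]
            if r + 1 < R:
                out[r * d:(r + 1) * d, (r + 1) * d:(r + 2) * d] = O[r]
                out[(r + 1) * d:(r + 2) * d, r * d:(r + 1) * d] = O[r].T
        return out

    def scale(self, c: float) -> "BlockTridiagonalSPD":
        return BlockTridiagonalSPD(ad.mul(self.diag, c) if isinstance(self.diag, ad.Tensor) else c * self.diag,
                                   ad.mul(self.offdiag, c) if isinstance(self.offdiag, ad.Tensor) else c * self.offdiag)


class BlockCholesky:
    """Lower factor L with diagonal blocks ``diag_chol[r]`` and subdiagonal
    blocks ``sub[r]`` at (r+1, r), such that P = L L^T."""

    def __init__(self, diag_chol, sub):
        self.diag_chol = diag_chol
        self.sub = sub

    @property
    def R(self):
        return len(self.diag_chol)


def factorize(P: BlockTridiagonalSPD) -> BlockCholesky:
    """Block Cholesky by forward recursion; raises DecompositionError with
    the failing block index on a non-PD input."""
    R = P.R
    diag = ad.as_tensor(P.diag)
    off = ad.as_tensor(P.offdiag)
    chols, subs = [], []
    schur = diag[0]
    for r in range(R):
        try:
            Lr = ad.cholesky(schur)
        except np.linalg.LinAlgError:
            raise DecompositionError(r) from None
        chols.append(Lr)
        if r + 1 < R:
            # S_r solves S_r L_r^T = O_r^T  =>  L_r S_r^T = O_r
            St = ad.solve_triangular(Lr, off[r], lower=True, trans=False)
            S = ad.swap_last(St)
            subs.append(S)
            schur = ad.add(diag[r + 1], ad.mul(ad.matmul(S, St), -1.0))
    return BlockCholesky(chols, subs)


def solve(P_or_factor, rhs):
    """Solve P x = rhs; rhs shape (R, d) or (R, d, k)."""
    f = P_or_factor if isinstance(P_or_factor, BlockCholesky) else factorize(P_or_factor)
    R = f.R
    rhs_t = ad.as_tensor(rhs)
    # forward: L y = b
    ys = []
    for r in range(R):
        b = rhs_t[r]
        if r > 0:
            b = ad.add(b, ad.mul(ad.matmul(f.sub[r - 1], ys[r - 1]), -1.0))
        ys.append(ad.solve_triangular(f.diag_chol[r], b, lower=True, trans=False))
    # backward: L^T x = y
    xs = [None] * R
    for r in range(R - 1, -1, -1):
        y = ys[r]
        if r + 1 < R:
            y = ad.add(y, ad.mul(ad.matmul(ad.swap_last(f.sub[r]), xs[r + 1]), -1.0))
        xs[r] = ad.solve_triangular(f.diag_chol[r], y, lower=True, trans=True)
    out = ad.stack(xs, axis=0)
    if isinstance(rhs, ad.Tensor) or out.requires_grad:
        return out
    return out.value


def logdet(P_or_factor):
    """log det P from the block Cholesky diagonal."""
    f = P_or_factor if isinstance(P_or_factor, BlockCholesky) else factorize(P_or_factor)
    d = ad.value_of(f.diag_chol[0]).shape[0]
    ii = (np.arange(d), np.arange(d))
    terms = [ad.tsum(ad.log(Lr[ii])) for Lr in f.diag_chol]
    total = terms[0]
    for t in terms[1:]:
        total = ad.add(total, t)
    total = ad.mul(total, 2.0)
    return total if total.requires_grad else float(total.value)


def sample_noise(P_or_factor, eps):
    """Colored draws u = L^{-T} eps with Cov(u) = P^{-1}.

    eps has shape (R, d, n) (n independent standard-normal columns per
    bin); returns the same shape.
    """
    f = P_or_factor if isinstance(P_or_factor, BlockCholesky) else factorize(P_or_factor)
    R = f.R
    eps_t = ad.as_tensor(eps)
    us = [None] * R
    for r in range(R - 1, -1, -1):
        b = eps_t[r]
        if r + 1 < R:
            b = ad.add(b, ad.mul(ad.matmul(ad.swap_last(f.sub[r]), us[r + 1]), -1.0))
        us[r] = ad.solve_triangular(f.diag_chol[r], b, lower=True, trans=True)
    return ad.stack(us, axis=0)


@dataclass
class PosteriorGaussian:
    """Gaussian over a state path: mean (R, d) + block-tridiagonal precision."""

    mean: object
    precision: BlockTridiagonalSPD

    def __post_init__(self):
        if ad.value_of(self.mean).shape[0] != self.precision.R:
            raise ValueError("mean / precision bin counts disagree")

    def sample(self, n_samples: int, seed) -> np.ndarray:
        """Draws of shape (n_samples, R, d); deterministic given seed."""
        rng = np.random.default_rng(seed)
        R, d = self.precision.R, self.precision.d
        eps = rng.standard_normal((R, d, n_samples))
        u = ad.value_of(sample_noise(self.precision, eps))   # (R, d, n)
        return np.moveaxis(u, -1, 0) + ad.value_of(self.mean)[None, :, :]
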