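"""Synthetic benchmark generator: Lorenz hidden dynamics driving a
marked inhomogeneous Poisson process with waveform-like marks.

The hidden state follows the Lorenz attractor (chaotic, nonlinear); the
observed covariate is either the full 3-D state or its [x1, x3]
projection.  Unsorted spikes come from a mixture joint mark intensity:
component l fires at rate

    lambda_l * exp( (t/T * c_l + (1 - t/T) * d_l)' x_t ),

i.e. an exponential tuning whose preferred direction drifts linearly in
time from d_l to c_l (as printed; the `swap_cd` flag swaps the roles for
the reading where c_l is the t=0 direction), and emits a mark through a
Gaussian decoder applied to a component-specific Gaussian latent —
producing smooth, spike-like waveform snippets.

Simulation is exact thinning (Ogata) against a per-window majorant of
the ground intensity evaluated along the (nearest-neighbor-in-time)
sampled state path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_data import CovariateSeries, MarkedEventSequence, save_dataset
from .nets import GaussianNet, make_affine_gaussian_net


@dataclass
class LorenzConfig:
    """Lorenz parameters (sigma, rho, gamma) + integration settings."""

    sigma: float = 10.0
    rho: float = 28.0
    gamma: float = 8.0 / 3.0
    dt_int: float = 1e-3
    x0: tuple = (1.0, 1.0, 1.0)
    T: float = 100.0

    def __post_init__(self):
        if self.dt_int <= 0 or self.T <= 0:
            raise ValueError("dt_int and T must be positive")

    def fixed_point(self):
        s = np.sqrt(self.gamma * (self.rho - 1.0))
        return np.array([s, s, self.rho - 1.0])


def _lorenz_rhs(x, cfg: LorenzConfig):
    return np.array([cfg.sigma * (x[1] - x[0]),
                     x[0] * (cfg.rho - x[2]) - x[1],
                     x[0] * x[1] - cfg.gamma * x[2]])


def lorenz_path(cfg: LorenzConfig, sample_dt: float) -> np.ndarray:
    """Fixed-step RK4 integration subsampled to `sample_dt`.

    Returns the path at t = sample_dt, 2*sample_dt, ..., T as an
    (n_steps, 3) array (the grid convention of CovariateSeries).
    """
    ratio = sample_dt / cfg.dt_int
    if sample_dt < cfg.dt_int or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("sample_dt must be an integer multiple of dt_int")
    ratio = int(round(ratio))
    n_out = int(round(cfg.T / sample_dt))
    x = np.asarray(cfg.x0, dtype=np.float64)
    h = cfg.dt_int
    out = np.empty((n_out, 3))
    for i in range(n_out):
        for _ in range(ratio):
            k1 = _lorenz_rhs(x, cfg)
            k2 = _lorenz_rhs(x + 0.5 * h * k1, cfg)
            k3 = _lorenz_rhs(x + 0.5 * h * k2, cfg)
            k4 = _lorenz_rhs(x + h * k3, cfg)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"Lorenz integration diverged at step {i}")
        out[i] = x
    return out


def make_covariate(path: np.ndarray, mode: str, dt: float) -> CovariateSeries:
    """'3D': the hidden state itself; '2D': the [x1, x3] projection."""
    path = np.asarray(path, dtype=np.float64)
    if mode == "3D":
        return CovariateSeries(dt, path)
    if mode == "2D":
        return CovariateSeries(dt, path[:, [0, 2]])
    raise ValueError(f"unknown covariate mode {mode!r}")


# ---------------------------------------------------------------------------
# mixture joint mark intensity
# ---------------------------------------------------------------------------

def default_waveform_decoder(d_z=2, n_samples=32, n_sites=1, seed=0) -> GaussianNet:
    """Synthetic affine z -> waveform decoder.

    The mean is a spike-like template (sharp negative deflection with a
    slow rebound) plus latent-modulated bump-shaped loading columns, with
    diagonal noise — a qualitative stand-in for extracellular waveform
    snippets (32 samples per site); the real recordings' decoder
    parameters are not published.
    """
    rng = np.random.default_rng(seed)
    D = n_samples * n_sites
    t = np.linspace(-1.0, 2.5, n_samples)
    template = -2.0 * np.exp(-0.5 * (t / 0.25) ** 2) + 0.6 * np.exp(-0.5 * ((t - 1.0) / 0.7) ** 2)
    A = np.zeros((d_z, D))
    for j in range(d_z):
        for s in range(n_sites):
            center = rng.uniform(-0.3, 0.8)
            width = rng.uniform(0.2, 0.5)
            A[j, s * n_samples:(s + 1) * n_samples] = \
                rng.uniform(0.4, 1.0) * np.exp(-0.5 * ((t - center) / width) ** 2)
    c = np.tile(template, n_sites)
    prec = np.full(D, 25.0)     # sd 0.2 per sample
    return make_affine_gaussian_net(A, c, prec)


@dataclass
class SyntheticMixtureIntensity:
    """Ground-truth mixture generator parameters.

    Component l: rate scale `lambda_l`, tuning directions `c_l`, `d_l`
    (3-vectors), latent prior N(mu_z_l, prec_z_l^-1) feeding a shared
    affine waveform decoder.
    """

    lambdas: np.ndarray          # (L_c,)
    c: np.ndarray                # (L_c, 3)
    d: np.ndarray                # (L_c, 3)
    z_means: np.ndarray          # (L_c, d_z)
    z_precs: np.ndarray          # (L_c, d_z) diagonal
    decoder: GaussianNet         # affine z -> D_k
    T: float
    swap_cd: bool = False

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=np.float64)
        if np.any(self.lambdas < 0):
            raise ValueError("component scales must be nonnegative")
        self.c = np.atleast_2d(np.asarray(self.c, dtype=np.float64))
        self.d = np.atleast_2d(np.asarray(self.d, dtype=np.float64))
        self.z_means = np.atleast_2d(np.asarray(self.z_means, dtype=np.float64))
        self.z_precs = np.atleast_2d(np.asarray(self.z_precs, dtype=np.float64))

    @property
    def n_components(self) -> int:
        return len(self.lambdas)

    @property
    def mark_dim(self) -> int:
        return self.decoder.out_dim

    def directions_at(self, t):
        """Tuning direction per component at time t (interpolated)."""
        w = np.clip(t / self.T, 0.0, 1.0)
        ce, de = (self.d, self.c) if self.swap_cd else (self.c, self.d)
        return w * ce + (1.0 - w) * de      # printed form: c weighted by t/T

    def component_rates(self, t, x):
        if not (0.0 <= t <= self.T + 1e-12):
            raise ValueError("t outside [0, T]")
        dirs = self.directions_at(t)
        return self.lambdas * np.exp(dirs @ np.asarray(x, dtype=np.float64))

    def mark_marginal_moments(self):
        """Closed-form marginal N(kappa | A'mu + c, A'Sz A + noise) per
        component (affine decoder).  Returns (means (L_c, D), covs)."""
        A = self.decoder.w_mean.value        # (d_z, D)
        c0 = self.decoder.b_mean.value
        _, noise_prec = self.decoder.forward_np(self.z_means[:1])
        noise_cov = np.diag(1.0 / noise_prec[0])
        means = self.z_means @ A + c0
        covs = np.stack([A.T @ np.diag(1.0 / self.z_precs[l]) @ A + noise_cov
                         for l in range(self.n_components)])
        return means, covs

    def mark_log_density(self, l, k):
        """Closed-form log marginal density of a mark under component l."""
        means, covs = self.mark_marginal_moments()
        from scipy.stats import multivariate_normal
        return multivariate_normal(mean=means[l], cov=covs[l]).logpdf(np.asarray(k))


def mixture_intensity(mix: SyntheticMixtureIntensity, t, x, k=None, n_mc=None, seed=0):
    """Joint mark intensity lambda(t, x, kappa) of the generator.

    With ``k=None`` returns the ground intensity (the exponential-tuning
    sum alone; the mark density integrates to one).  The mark factor is
    closed-form for the affine decoder; pass ``n_mc`` to force a
    Monte-Carlo estimate instead (cross-check path).
    """
    rates = mix.component_rates(t, x)
    if k is None:
        return float(rates.sum())
    total = 0.0
    for l in range(mix.n_components):
        if n_mc is None:
            logd = mix.mark_log_density(l, k)
        else:
            rng = np.random.default_rng(seed + l)
            z = mix.z_means[l] + rng.standard_normal((n_mc, len(mix.z_means[l]))) / np.sqrt(mix.z_precs[l])
            m, p = mix.decoder.forward_np(z)
            resid = np.asarray(k) - m
            logs = 0.5 * (np.sum(np.log(p), axis=1) - np.sum(p * resid ** 2, axis=1)) \
                - 0.5 * len(np.asarray(k)) * np.log(2 * np.pi)
            from scipy.special import logsumexp
            logd = logsumexp(logs) - np.log(n_mc)
        total += rates[l] * np.exp(logd)
    return float(total)


def default_mixture(n_components=4, T=100.0, seed=0, direction_scale=0.08,
                    rate_scale=4.0, d_z=2, n_samples=32, n_sites=1) -> SyntheticMixtureIntensity:
    """Generator defaults: 4 components per probe, unit tuning directions
    scaled to 0.08 (Lorenz coordinates are O(10)), per-component base
    rate 4 /s, 2-D latent with a shared 32-sample waveform decoder."""
    rng = np.random.default_rng(seed)
    def unit_dirs(n):
        v = rng.standard_normal((n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    z_means = rng.normal(0.0, 1.5, (n_components, d_z))
    z_precs = np.full((n_components, d_z), 8.0)     # tight clusters in z
    return SyntheticMixtureIntensity(
        lambdas=np.full(n_components, rate_scale),
        c=direction_scale * unit_dirs(n_components),
        d=direction_scale * unit_dirs(n_components),
        z_means=z_means, z_precs=z_precs,
        decoder=default_waveform_decoder(d_z, n_samples, n_sites, seed=seed + 17),
        T=T)


# ---------------------------------------------------------------------------
# simulation by thinning
# ---------------------------------------------------------------------------

def ground_intensity_on_grid(mix: SyntheticMixtureIntensity, path, sample_dt):
    """Per-grid-point ground intensity along the path (t_j = j*sample_dt)."""
    n = len(path)
    tt = (np.arange(1, n + 1)) * sample_dt
    w = np.clip(tt / mix.T, 0.0, 1.0)[:, None, None]
    ce, de = (mix.d, mix.c) if mix.swap_cd else (mix.c, mix.d)
    dirs = w * ce[None] + (1 - w) * de[None]        # (n, L_c, 3)
    expo = np.einsum("nlj,nj->nl", dirs, path)
    return (mix.lambdas[None, :] * np.exp(expo)).sum(axis=1), \
        mix.lambdas[None, :] * np.exp(expo)


def simulate_spikes(mix: SyntheticMixtureIntensity, path, sample_dt, seed=0,
                    window=1.0, safety=1.2) -> MarkedEventSequence:
    """Exact thinning against per-window majorants of the ground intensity.

    The state along the path is piecewise-constant (nearest-neighbor in
    time), so the grid maximum times a safety factor is a true majorant;
    if the exact intensity ever exceeds it, the majorant is inflated and
    the window replayed (warned).  Accepted events draw a component with
    probability proportional to its intensity, then z from the component
    prior and the mark from the decoder.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    path = np.asarray(path, dtype=np.float64)
    n_grid = len(path)
    T = n_grid * sample_dt
    ground, per_comp = ground_intensity_on_grid(mix, path, sample_dt)
    if not np.all(np.isfinite(ground)):
        raise FloatingPointError("non-finite ground intensity along the path")
    times, comps = [], []
    n_win = int(np.ceil(T / window))
    for wdx in range(n_win):
        t0, t1 = wdx * window, min((wdx + 1) * window, T)
        j0 = max(0, int(np.floor(t0 / sample_dt)) - 1)
        j1 = min(int(np.ceil(t1 / sample_dt)) + 1, n_grid)
        lam_star = ground[j0:j1].max() * safety
        if lam_star <= 0:
            continue
        while True:
            # replayable homogeneous proposal stream for this window
            sub = np.random.default_rng(rng.integers(2 ** 31 - 1))
            t = t0
            ok = True
            cand_t, cand_c = [], []
            while True:
                t = t + sub.exponential(1.0 / lam_star)
                if t >= t1:
                    break
                j = min(max(int(np.floor(t / sample_dt + 0.5 + 1e-9)), 1), n_grid) - 1
                lam_t = ground[j]
                if lam_t > lam_star:
                    import warnings
                    warnings.warn("majorant violated; inflating")
                    lam_star = lam_t * safety
                    ok = False
                    break
                if sub.uniform() < lam_t / lam_star:
                    cand_t.append(t)
                    probs = per_comp[j] / per_comp[j].sum()
                    cand_c.append(sub.choice(mix.n_components, p=probs))
            if ok:
                times.extend(cand_t)
                comps.extend(cand_c)
                break
    times = np.asarray(times)
    comps = np.asarray(comps, dtype=int)
    order = np.argsort(times, kind="stable")
    times, comps = times[order], comps[order]
    D = mix.mark_dim
    marks = np.empty((len(times), D))
    for i, l in enumerate(comps):
        z = mix.z_means[l] + rng.standard_normal(mix.z_means.shape[1]) / np.sqrt(mix.z_precs[l])
        m, p = mix.decoder.forward_np(z[None, :])
        marks[i] = m[0] + rng.standard_normal(D) / np.sqrt(p[0])
    return MarkedEventSequence(times, marks, T)


def cumulative_ground_intensity(mix, path, sample_dt, times):
    """Integral of the (piecewise-constant) ground intensity up to each
    time; the time-rescaling transform for the exactness check."""
    ground, _ = ground_intensity_on_grid(mix, path, sample_dt)
    n = len(ground)
    # nearest-neighbor cell j (grid point t_j = j*dt) covers
    # ((j-0.5)dt, (j+0.5)dt], truncated to (0, n*dt]
    edges = np.concatenate([[0.0], (np.arange(1, n) + 0.5) * sample_dt, [n * sample_dt]])
    cum = np.concatenate([[0.0], np.cumsum(ground * np.diff(edges))])
    return np.interp(np.asarray(times), edges, cum)


# ---------------------------------------------------------------------------
# trial bundles
# ---------------------------------------------------------------------------

def make_trials(out_dir, n_trials, seeds=None, T=100.0, dt=0.01, n_probes=4,
                n_components=4, mode="3D", lorenz: LorenzConfig = None,
                swap_cd=False, fmt="h5"):
    """Generate trial datasets on disk + a JSON manifest of contiguous
    80/10/10 train/validation/test splits (whole bins; remainder to
    training).  Each trial integrates its own Lorenz path from a seeded
    random initial condition near the attractor."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = list(seeds) if seeds is not None else list(range(n_trials))
    if len(seeds) != n_trials:
        raise ValueError("need one seed per trial")
    manifest = {"trials": [], "dt": dt, "T": T, "mode": mode}
    R = int(round(T / dt))
    n_test = R // 10
    n_val = R // 10
    n_train = R - n_val - n_test
    for i, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        cfg = lorenz or LorenzConfig(T=T)
        cfg = LorenzConfig(sigma=cfg.sigma, rho=cfg.rho, gamma=cfg.gamma,
                           dt_int=cfg.dt_int, T=T,
                           x0=tuple(np.array([1.0, 1.0, 25.0]) + rng.normal(0, 3.0, 3)))
        path = lorenz_path(cfg, dt)
        cov = make_covariate(path, mode, dt)
        seqs = []
        for p in range(n_probes):
            mix = default_mixture(n_components, T=T, seed=int(rng.integers(2 ** 31 - 1)),
                                  n_sites=1)
            mix.swap_cd = swap_cd
            seq = simulate_spikes(mix, path, dt, seed=int(rng.integers(2 ** 31 - 1)))
            seq.probe_id = f"probe{p}"
            seqs.append(seq)
        fname = out_dir / f"trial{i:02d}.{fmt}"
        save_dataset(fname, seqs, cov)
        manifest["trials"].append({
            "file": fname.name, "seed": int(seed),
            "split_bins": {"train": [0, n_train],
                           "val": [n_train, n_train + n_val],
                           "test": [n_train + n_val, R]}})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir / "manifest.json"
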