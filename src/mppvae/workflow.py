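"""End-to-end experiment pipelines.

Glue for the full study loop on synthetic data: generate a Lorenz trial,
bin it, train the state-space model with the marked-point-process
observation, evaluate held-out NLL, decode the covariate from spikes
alone, run the GMM baseline on the same data, and feed the paired fold
scores to the Wilcoxon / Holm-Sidak comparison harness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import baselines, decoding, state_space, synthetic
from .bounds import BoundConfig
from .core_data import BinnedDataset, CovariateSeries, MarkedEventSequence, bin_events
from .jmi_vae import build_model
from .state_space import SSMTrainConfig, StateSpaceModel, StructuredVariationalFamily


def split_binned(data: BinnedDataset, train_frac=0.8, val_frac=0.1):
    """Contiguous train/validation/test split over bins (whole bins;
    remainder goes to training)."""
    R = data.R
    n_test = int(round(R * (1.0 - train_frac - val_frac)))
    n_val = int(round(R * val_frac))
    n_train = R - n_val - n_test
    return (data.slice(0, n_train), data.slice(n_train, n_train + n_val),
            data.slice(n_train + n_val, R))


def fit_ar1(y):
    """Least-squares AR(1) prior y_{r+1} = F y_r + a + e, e ~ N(0, V^-1):
    the linear-Gaussian chain used for baseline decoding in covariate
    space."""
    y = np.asarray(y, dtype=np.float64)
    X = np.hstack([y[:-1], np.ones((len(y) - 1, 1))])
    coef, *_ = np.linalg.lstsq(X, y[1:], rcond=None)
    F = coef[:-1].T
    a = coef[-1]
    resid = y[1:] - X @ coef
    cov = np.cov(resid.T) + 1e-8 * np.eye(y.shape[1])
    V = np.linalg.inv(np.atleast_2d(cov))
    a1 = y.mean(axis=0)
    V1 = np.linalg.inv(np.atleast_2d(np.cov(y.T)) + 1e-8 * np.eye(y.shape[1]))
    return a1, V1, F, a, V


@dataclass
class SyntheticExperimentConfig:
    T: float = 20.0
    dt: float = 0.01
    n_probes: int = 1
    n_components: int = 4
    mode: str = "3D"
    d_x: int = 10
    d_z: int = 4
    hidden: tuple = (64, 64)
    bound: BoundConfig = field(default_factory=BoundConfig)
    train: SSMTrainConfig = field(default_factory=lambda: SSMTrainConfig(epochs=40, lr=3e-3))
    gmm_components: int = 16
    gmm_iters: int = 300
    decode_L: int = 32
    decode_samples: int = 1000
    n_folds: int = 8
    seed: int = 0


def generate_trial(cfg: SyntheticExperimentConfig, seed=None):
    """One Lorenz trial: covariate series + one merged spike sequence.

    Spikes from all probes are merged into a single mark stream (marks
    from different probes occupy the same 32-sample space here since the
    scaled study uses one probe by default)."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    lz = synthetic.LorenzConfig(T=cfg.T, x0=tuple(np.array([1.0, 1.0, 25.0]) + rng.normal(0, 3.0, 3)))
    path = synthetic.lorenz_path(lz, cfg.dt)
    cov = synthetic.make_covariate(path, cfg.mode, cfg.dt)
    seqs = []
    for p in range(cfg.n_probes):
        mix = synthetic.default_mixture(cfg.n_components, T=cfg.T,
                                        seed=int(rng.integers(2 ** 31 - 1)))
        seqs.append(synthetic.simulate_spikes(mix, path, cfg.dt,
                                              seed=int(rng.integers(2 ** 31 - 1))))
    times = np.concatenate([s.times for s in seqs])
    marks = np.concatenate([s.marks for s in seqs], axis=0)
    order = np.argsort(times, kind="stable")
    seq = MarkedEventSequence(times[order], marks[order], cfg.T)
    return seq, cov


def run_synthetic_experiment(cfg: SyntheticExperimentConfig = None, seed=None,
                             verbose=False):
    """The scaled study loop on one trial; returns a dict of metrics.

    Keys: elbo_init / elbo_trained (validation), nll_test, mse_jvae,
    mse_gmm, mse_mean_baseline, per-fold score table, and the
    Wilcoxon/Holm-Sidak comparison frame.
    """
    cfg = cfg or SyntheticExperimentConfig()
    seed = cfg.seed if seed is None else seed
    seq, cov = generate_trial(cfg, seed)
    data = bin_events(seq, cov, cfg.dt)
    train, val, test = split_binned(data)
    d_y, d_k = cov.dim, seq.mark_dim

    # standardize the covariate with training statistics: the tanh networks
    # expect O(1) inputs/outputs (Lorenz coordinates are O(10-20))
    mu_y = train.y.mean(axis=0)
    sd_y = train.y.std(axis=0) + 1e-12
    train, val, test = (BinnedDataset(s.dt_bin, s.R, (s.y - mu_y) / sd_y,
                                      s.mark_sets, s.counts)
                        for s in (train, val, test))

    jmi = build_model(cfg.d_x, d_k, cfg.d_z, hidden=cfg.hidden, seed=seed,
                      bound_cfg=cfg.bound)
    model = StateSpaceModel(cfg.d_x, d_y, jmi, hidden=cfg.hidden, seed=seed + 1)
    q = StructuredVariationalFamily(cfg.d_x, d_y, d_k, hidden=cfg.hidden, seed=seed + 2)

    tc = cfg.train
    tc.seed = seed
    rate = max(train.total_events, 1) / (train.R * train.dt_bin)
    model.jmi.log_lambda0.value = np.array(np.log(rate))
    elbo_init = float(ad.value_of(state_space.elbo(model, q, val, n_mc=tc.val_n_mc,
                                                   seed=seed + 999)))
    model, q, trace = state_space.fit(model, q, train, tc, val_data=val)
    elbo_trained = max(trace["val"]) if trace["val"] else elbo_init
    if verbose:
        print(f"ELBO val: init {elbo_init:.1f} -> trained {elbo_trained:.1f}")

    nll_test = state_space.predict_nll(model, q, test, n_mc=tc.val_n_mc, seed=seed + 5)

    # --- decoding from spikes alone (test segment) ---
    dyn = model.dyn
    dyn_mats = (dyn.a1.value, ad.value_of(dyn.V1p.matrix()), dyn.F.value,
                dyn.a.value, ad.value_of(dyn.Vp.matrix()))
    prov = decoding.JMIBinTermProvider(model.jmi, test, L_dec=cfg.decode_L,
                                       seed=seed + 6)
    lap = decoding.newton_map(dyn_mats, prov, test.R, K_max=25, seed=seed + 7)
    y_hat_s, y_var_s = decoding.decode_covariate(model, lap, S=cfg.decode_samples,
                                                 seed=seed + 8)
    # back to original covariate units
    y_hat = y_hat_s * sd_y + mu_y
    y_var = y_var_s * sd_y ** 2
    y_test = test.y * sd_y + mu_y
    y_train_mean = train.y.mean(axis=0) * sd_y + mu_y
    mse_jvae = decoding.decode_mse(y_hat, y_test)
    mse_mean = decoding.decode_mse(np.tile(y_train_mean, (test.R, 1)), y_test)

    # --- GMM baseline over the observed covariate ---
    xs_spk, ks_spk = _spike_states(train)
    gmm, gtrace = baselines.gmm_fit(xs_spk, ks_spk, train.y,
                                    n_components=cfg.gmm_components, dt=cfg.dt,
                                    n_iter=cfg.gmm_iters, seed=seed)
    ar = fit_ar1(train.y)
    gprov = baselines.GMMBinTermProvider(gmm, test)
    glap = decoding.newton_map(ar, gprov, test.R, K_max=25, seed=seed + 9)
    y_gmm = glap.mean * sd_y + mu_y
    mse_gmm = decoding.decode_mse(y_gmm, y_test)
    xs_t, ks_t = _spike_states(test)
    gmm_nll_test = -baselines.gmm_loglik(gmm, xs_t, ks_t, test.y, dt=cfg.dt)

    # --- per-fold paired scores + comparison harness ---
    folds = _fold_slices(test.R, cfg.n_folds)
    rows = []
    for i, (a, b) in enumerate(folds):
        rows.append({
            "fold": i,
            "JVAE": decoding.decode_mse(y_hat[a:b], y_test[a:b]),
            "GMM": decoding.decode_mse(y_gmm[a:b], y_test[a:b]),
            "MeanPredictor": decoding.decode_mse(
                np.tile(y_train_mean, (b - a, 1)), y_test[a:b]),
        })
    fold_mse = pd.DataFrame(rows).set_index("fold")
    comparison = baselines.wilcoxon_holm_sidak(fold_mse)

    return {
        "elbo_init": elbo_init, "elbo_trained": elbo_trained,
        "train_trace": trace, "nll_test": nll_test, "gmm_nll_test": gmm_nll_test,
        "mse_jvae": mse_jvae, "mse_gmm": mse_gmm, "mse_mean_baseline": mse_mean,
        "decoded_mean": y_hat, "decoded_var": y_var, "y_test": y_test,
        "y_scale": (mu_y, sd_y), "laplace": lap,
        "fold_mse": fold_mse, "comparison": comparison,
        "model": model, "q": q, "gmm": gmm, "test": test, "train": train,
    }


def _spike_states(data: BinnedDataset):
    """States (bin covariates) at spikes + stacked marks."""
    xs, ks = [], []
    for r in range(data.R):
        n_r = data.counts[r]
        if n_r:
            xs.append(np.tile(data.y[r], (n_r, 1)))
            ks.append(np.asarray(data.mark_sets[r], dtype=np.float64))
    if not xs:
        return np.zeros((0, data.y.shape[1])), np.zeros((0, 1))
    return np.concatenate(xs), np.concatenate(ks)


def _fold_slices(R, n_folds):
    edges = np.linspace(0, R, n_folds + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_folds)]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: StateSpaceModel, q: StructuredVariationalFamily):
    meta = {"d_x": model.d_x, "d_y": model.d_y, "d_k": model.jmi.d_k,
            "d_z": model.jmi.d_z, "hidden": list(model.obs_y.hidden),
            "bound": model.jmi.bound_cfg.to_dict()}
    arrays = {f"model.{k}": v for k, v in model.state_dict().items()}
    arrays.update({f"q.{k}": v for k, v in q.state_dict().items()})
    np.savez(path, __meta__=json.dumps(meta), **arrays)
    return path


def load_checkpoint(path):
    with np.load(path) as f:
        meta = json.loads(str(f["__meta__"]))
        jmi = build_model(meta["d_x"], meta["d_k"], meta["d_z"],
                          hidden=tuple(meta["hidden"]),
                          bound_cfg=BoundConfig.from_dict(meta["bound"]))
        model = StateSpaceModel(meta["d_x"], meta["d_y"], jmi,
                                hidden=tuple(meta["hidden"]))
        q = StructuredVariationalFamily(meta["d_x"], meta["d_y"], meta["d_k"],
                                        hidden=tuple(meta["hidden"]))
        model.load_state_dict({k[6:]: f[k] for k in f.files if k.startswith("model.")})
        q.load_state_dict({k[2:]: f[k] for k in f.files if k.startswith("q.")})
    return model, q
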