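"""Data model for unsorted spikes and covariates.

Unsorted ("clusterless") spiking activity is a sequence of event times
with an attached mark vector per event — here a waveform snippet — on an
observation interval (0, T].  The covariate (stimulus, position, ...) is
measured on a regular grid with spacing ``dt``.  This module provides the
containers, the time binning used by the state-space model, the
nearest-neighbor state interpolation used by the observed-state
likelihood, and HDF5/NPZ round-trip IO.

Conventions (documented, deterministic):

* bins are left-open/right-closed: event t belongs to bin r iff
  t in ((r-1)*dt_bin, r*dt_bin], matching the (0, T] interval;
* the covariate grid is t_j = j*dt, j = 1..m; nearest-neighbor midpoint
  ties resolve to the *later* grid point;
* y_r for a bin is the covariate at the bin's right edge;
* duplicate spike times are permitted (distinct marks) and preserved in
  input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import h5py


class FormatError(ValueError):
    """Raised when an on-disk dataset does not match the documented layout."""


@dataclass
class MarkedEventSequence:
    """Spike times with mark vectors on (0, T]."""

    times: np.ndarray            # (n,) float64, seconds, non-decreasing
    marks: np.ndarray            # (n, D_k) float64
    duration_T: float
    probe_id: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64).reshape(-1)
        self.marks = np.asarray(self.marks, dtype=np.float64)
        if self.marks.ndim == 1:
            self.marks = self.marks.reshape(len(self.times), -1) if len(self.times) else self.marks.reshape(0, 1)
        if len(self.times) != self.marks.shape[0]:
            raise ValueError(f"times ({len(self.times)}) and marks ({self.marks.shape[0]}) disagree")
        if len(self.times):
            if np.any(np.diff(self.times) < 0):
                raise ValueError("spike times must be sorted non-decreasing")
            if self.times[0] <= 0 or self.times[-1] > self.duration_T + 1e-12:
                raise ValueError("spike times must lie in (0, T]")

    @property
    def n_events(self) -> int:
        return len(self.times)

    @property
    def mark_dim(self) -> int:
        return self.marks.shape[1]


@dataclass
class CovariateSeries:
    """Covariate values y at grid points t_j = j*dt, j = 1..m."""

    dt: float
    values: np.ndarray           # (m, D_y) float64

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariate contains non-finite entries; impute upstream")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    @property
    def span(self) -> float:
        return self.m * self.dt


@dataclass
class BinnedDataset:
    """Regular time bins holding the covariate y_r and per-bin mark sets."""

    dt_bin: float
    R: int
    y: np.ndarray                # (R, D_y)
    mark_sets: list = field(default_factory=list)   # R arrays (n_r, D_k)
    counts: np.ndarray = None    # (R,) int

    def __post_init__(self):
        self.y = np.atleast_2d(np.asarray(self.y, dtype=np.float64))
        if self.counts is None:
            self.counts = np.array([len(m) for m in self.mark_sets], dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.mark_sets) != self.R or self.y.shape[0] != self.R:
            raise ValueError("bin count mismatch")

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    def slice(self, start: int, stop: int) -> "BinnedDataset":
        """Contiguous sub-range of bins [start, stop)."""
        return BinnedDataset(self.dt_bin, stop - start, self.y[start:stop],
                             [self.mark_sets[r] for r in range(start, stop)],
                             self.counts[start:stop])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def bin_events(seq: MarkedEventSequence, cov: CovariateSeries, dt_bin: float) -> BinnedDataset:
    """Split the time axis into R equal bins; assign events and decimate y.

    Event t goes to bin r iff t in ((r-1)*dt_bin, r*dt_bin].  y_r is the
    covariate at the bin's right-edge grid point.
    """
    if dt_bin <= 0:
        raise ValueError("dt_bin must be positive")
    step = dt_bin / cov.dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError("dt_bin must be an integer multiple of the covariate dt")
    step = int(round(step))
    R = cov.m // step
    horizon = R * dt_bin
    if seq.n_events and seq.times[-1] > horizon + 1e-12:
        raise ValueError(f"event time {seq.times[-1]} beyond binned horizon {horizon}")
    y = cov.values[step - 1::step][:R]
    idx = np.ceil(seq.times / dt_bin - 1e-12).astype(int)  # 1-based bin index
    idx = np.clip(idx, 1, R)
    mark_sets = [seq.marks[idx == r + 1] for r in range(R)]
    return BinnedDataset(dt_bin, R, y, mark_sets)


def state_at_spikes(cov: CovariateSeries, times) -> np.ndarray:
    """Covariate value at the grid point nearest each spike time.

    Midpoint ties resolve to the later grid point.
    """
    t = np.asarray(times, dtype=np.float64).reshape(-1)
    if t.size and (t.min() <= 0 or t.max() > cov.span + 1e-12):
        raise ValueError("spike time outside the covariate grid span")
    j = np.floor(t / cov.dt + 0.5 + 1e-9).astype(int)
    j = np.clip(j, 1, cov.m)
    return cov.values[j - 1]


# ---------------------------------------------------------------------------
# IO: HDF5 layout (NPZ mirror by file suffix)
#   /spikes/<probe>/times [n], /spikes/<probe>/marks [n, D_k]
#   /covariate/dt, /covariate/values [m, D_y], /meta/duration_T
# ---------------------------------------------------------------------------

def save_dataset(path, sequences, cov: CovariateSeries):
    """Write sequences + covariate; format chosen by suffix (.h5/.npz)."""
    path = str(path)
    seqs = sequences if isinstance(sequences, (list, tuple)) else [sequences]
    if path.endswith(".npz"):
        payload = {"covariate/dt": np.float64(cov.dt), "covariate/values": cov.values,
                   "meta/duration_T": np.float64(seqs[0].duration_T)}
        for i, s in enumerate(seqs):
            name = s.probe_id or f"probe{i}"
            payload[f"spikes/{name}/times"] = s.times
            payload[f"spikes/{name}/marks"] = s.marks
        np.savez(path, **payload)
    else:
        with h5py.File(path, "w") as f:
            for i, s in enumerate(seqs):
                name = s.probe_id or f"probe{i}"
                g = f.create_group(f"spikes/{name}")
                g.create_dataset("times", data=s.times)
                g.create_dataset("marks", data=s.marks)
            f.create_dataset("covariate/dt", data=cov.dt)
            f.create_dataset("covariate/values", data=cov.values)
            f.create_dataset("meta/duration_T", data=seqs[0].duration_T)
    return path


def load_dataset(path):
    """Read the documented layout; returns (list of sequences, covariate)."""
    path = str(path)
    if path.endswith(".npz"):
        with np.load(path) as f:
            keys = set(f.files)
            for req in ("covariate/dt", "covariate/values", "meta/duration_T"):
                if req not in keys:
                    raise FormatError(f"missing key {req!r}")
            probes = sorted({k.split("/")[1] for k in keys if k.startswith("spikes/")})
            if not probes:
                raise FormatError("missing group 'spikes'")
            T = float(f["meta/duration_T"])
            seqs = []
            for name in probes:
                if f"spikes/{name}/times" not in keys:
                    raise FormatError(f"missing key 'spikes/{name}/times'")
                if f"spikes/{name}/marks" not in keys:
                    raise FormatError(f"missing key 'spikes/{name}/marks'")
                seqs.append(MarkedEventSequence(f[f"spikes/{name}/times"],
                                                np.asarray(f[f"spikes/{name}/marks"], dtype=np.float64),
                                                T, probe_id=name))
            cov = CovariateSeries(float(f["covariate/dt"]), f["covariate/values"])
        return seqs, cov
    with h5py.File(path, "r") as f:
        for req in ("covariate/dt", "covariate/values", "meta/duration_T", "spikes"):
            if req not in f:
                raise FormatError(f"missing group/field {req!r}")
        T = float(f["meta/duration_T"][()])
        seqs = []
        for name in sorted(f["spikes"].keys()):
            g = f["spikes"][name]
            for req in ("times", "marks"):
                if req not in g:
                    raise FormatError(f"missing key 'spikes/{name}/{req}'")
            seqs.append(MarkedEventSequence(np.asarray(g["times"], dtype=np.float64),
                                            np.asarray(g["marks"], dtype=np.float64),
                                            T, probe_id=name))
        cov = CovariateSeries(float(f["covariate/dt"][()]),
                              np.asarray(f["covariate/values"], dtype=np.float64))
    return seqs, cov
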