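"""Connectome-coupled network of mean-field regions with axonal delays.

Each of the N regions is a two-population (RS/FS) mean-field with adaptation;
regions exchange excitatory rate through the connectome.  The excitatory
input of region k is

    nu_input(k, t) = nu_drive(k, t) + nu_e(k, t) + S * sum_{j != k} C_jk nu_e(j, t - d_jk),

i.e. the self term enters with unit coupling (C_kk = 1) and the global
coupling strength S scales all long-range terms; d_jk = tract_length / v_c.
Both the excitatory and inhibitory transfer functions receive
nu_input + nu_aff.  A square-wave stimulus can be injected into the
excitatory transfer-function input of one target region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

from . import _kernels as K
from .connectome import Connectome, compute_delays, DEFAULT_AXONAL_SPEED
from .params import MeanFieldParams
from .mean_field import MeanFieldState

__all__ = ["BrainSimConfig", "StimulusSpec", "RegionalTimeSeries",
           "coupling_input", "simulate_brain"]


@dataclass
class StimulusSpec:
    """Square-wave rate stimulus to one region's excitatory TF input."""

    region: object = "rh-premotor"      # label (partial match) or index
    amplitude: float = 0.1              # Hz
    duration: float = 50.0              # ms
    onset: float = 2000.0               # ms

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be nonnegative")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")


@dataclass
class BrainSimConfig:
    """Whole-brain simulation settings (single parameter set shared across
    regions, as appropriate for a homogeneous-cortex model)."""

    connectome: Connectome = None
    mf: MeanFieldParams = field(default_factory=MeanFieldParams)
    S: float = 0.1                      # global coupling strength
    v_c: float = DEFAULT_AXONAL_SPEED   # axonal speed, mm/ms
    duration: float = 10_000.0          # ms
    dt: float = 0.1                     # ms
    transient: float = 2_000.0          # ms discarded by analyses
    seed: int = 0
    record_dt: float = 1.0              # ms (1 kHz output)

    def __post_init__(self):
        if self.S < 0:
            raise ValueError("coupling strength S must be nonnegative")
        if self.duration <= self.transient:
            raise ValueError("duration must exceed the transient")


@dataclass
class RegionalTimeSeries:
    """Per-region rate and adaptation series (Hz / pA), regions x time."""

    t: np.ndarray                       # ms
    nu_e: np.ndarray                    # (n_regions, n_samples)
    nu_i: np.ndarray
    W: np.ndarray
    labels: list
    dt: float                           # sampling step, ms
    transient: float = 0.0              # ms

    @property
    def n_regions(self) -> int:
        return self.nu_e.shape[0]

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt

    def post_transient(self) -> "RegionalTimeSeries":
        i0 = int(round(self.transient / self.dt))
        return RegionalTimeSeries(t=self.t[i0:], nu_e=self.nu_e[:, i0:],
                                  nu_i=self.nu_i[:, i0:], W=self.W[:, i0:],
                                  labels=self.labels, dt=self.dt, transient=0.0)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["dt_ms"] = self.dt
            fh.attrs["transient_ms"] = self.transient
            fh.create_dataset("t_ms", data=self.t)
            fh.create_dataset("nu_e_hz", data=self.nu_e)
            fh.create_dataset("nu_i_hz", data=self.nu_i)
            fh.create_dataset("W_pA", data=self.W)
            fh.create_dataset("labels",
                              data=np.array([str(x) for x in self.labels],
                                            dtype=h5py.string_dtype()))

    @classmethod
    def from_hdf5(cls, path) -> "RegionalTimeSeries":
        with h5py.File(path, "r") as fh:
            return cls(t=fh["t_ms"][:], nu_e=fh["nu_e_hz"][:],
                       nu_i=fh["nu_i_hz"][:], W=fh["W_pA"][:],
                       labels=[x.decode() if isinstance(x, bytes) else str(x)
                               for x in fh["labels"][:]],
                       dt=float(fh.attrs["dt_ms"]),
                       transient=float(fh.attrs["transient_ms"]))

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.nu_e.T, index=self.t, columns=self.labels)
        df.index.name = "t_ms"
        df.to_csv(path)


def coupling_input(k: int, step: int, history: np.ndarray,
                   conn: Connectome, delays: np.ndarray, S: float,
                   dt: float) -> float:
    """Long-range + self excitatory input of region k at a given step (Hz).

    ``history``: (n_steps_so_far, n_regions) array of past excitatory rates in
    Hz (row ``step`` = current time).  Reference implementation of the
    coupling used by the fast integrator; mainly for tests and inspection.
    """
    n = conn.n_regions
    lag = np.rint(delays / dt).astype(np.int64)
    acc = history[step, k]      # self term, C_kk = 1, undelayed, unscaled
    for j in range(n):
        if j == k:
            continue
        c = conn.weights[j, k]
        if c == 0.0:
            continue
        s = step - lag[j, k]
        if s < 0:
            raise IndexError("requested lag reaches beyond the history buffer")
        acc += S * c * history[s, j]
    return acc


def simulate_brain(config: BrainSimConfig,
                   stimulus: Optional[StimulusSpec] = None,
                   init: Optional[MeanFieldState] = None) -> RegionalTimeSeries:
    """Heun integration of the delay-coupled whole-brain model.

    Per-region OU drives are independent, with per-region streams derived
    deterministically from the master seed.  The delay buffer is warmed up
    with the initial rates.
    """
    conn = config.connectome
    if conn is None:
        raise ValueError("config.connectome is required")
    mf = config.mf.with_tfs()
    adex = mf.adex
    n = conn.n_regions
    dt = config.dt
    if dt > mf.T / 10:
        raise ValueError("dt must be <= T/10")
    delays = compute_delays(conn, config.v_c)
    lag = np.rint(delays / dt).astype(np.int64)
    np.fill_diagonal(lag, 0)

    C_off = conn.weights * config.S
    np.fill_diagonal(C_off, 0.0)

    n_steps = int(round(config.duration / dt))
    stride = max(1, int(round(config.record_dt / dt)))
    n_rec = (n_steps + stride - 1) // stride
    out_e = np.empty((n_rec, n))
    out_i = np.empty((n_rec, n))
    out_w = np.empty((n_rec, n))

    if init is None:
        init = MeanFieldState(0.5, 1.0, 0.0)
    ne0 = np.full(n, init.nu_e * 1e-3)
    ni0 = np.full(n, init.nu_i * 1e-3)
    W0 = np.full(n, init.W)

    if stimulus is not None:
        stim_k = conn.region_index(stimulus.region)
        stim_amp = stimulus.amplitude * 1e-3
        stim_on = int(round(stimulus.onset / dt))
        stim_off = int(round((stimulus.onset + stimulus.duration) / dt))
    else:
        stim_k, stim_amp, stim_on, stim_off = -1, 0.0, 0, 0

    status = K.sim_brain(
        n_steps, dt, mf.T, mf.tf_e.P, mf.tf_i.P, mf.tf_e.cfg, mf.tf_i.cfg,
        adex.b, adex.a, adex.u_w, C_off, lag,
        mf.drive.mean * 1e-3, mf.drive.sd * 1e-3, mf.drive.tau,
        mf.nu_aff * 1e-3,
        stim_k, stim_amp, stim_on, stim_off,
        ne0, ni0, W0, int(config.seed) % (2**31 - 1), stride,
        out_e, out_i, out_w)
    if status != 0:
        raise FloatingPointError("brain simulation produced non-finite state")
    t = np.arange(n_rec) * stride * dt
    return RegionalTimeSeries(t=t, nu_e=out_e.T * 1e3, nu_i=out_i.T * 1e3,
                              W=out_w.T, labels=list(conn.labels), dt=stride * dt,
                              transient=config.transient)
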