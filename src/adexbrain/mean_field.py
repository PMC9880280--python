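"""Single-region two-population mean-field of the AdEx network.

The model describes excitatory (RS) and inhibitory (FS) population rates
nu_e, nu_i plus the excitatory adaptation current W, driven by an
Ornstein-Uhlenbeck afferent-rate fluctuation applied to the excitatory
transfer-function input.  Two closures are available:

* first order: T dnu/dt = F(nu) - nu (Wilson-Cowan-like);
* second order (Master Equation): rates corrected by the covariance term
  (1/2) c_lh d2F/dnu_l dnu_h, with the 2x2 rate covariance c integrated
  alongside (finite-size source term ~ 1/N).

With b = 0 the system fluctuates around a high-rate fixed point (wake-like);
with b = 60 pA adaptation buildup destabilizes the high-rate fixed point and
the system alternates between high-rate and near-silent states (slow waves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .params import MeanFieldParams

__all__ = [
    "MeanFieldState",
    "MeanFieldTrajectory",
    "simulate_first_order",
    "simulate_second_order",
    "find_fixed_points",
]

_FD_H = 5e-4     # kHz; finite-difference step for TF derivatives


@dataclass
class MeanFieldState:
    """Instantaneous mean-field state (rates in Hz, W in pA, c in Hz^2)."""

    nu_e: float
    nu_i: float
    W: float
    c: np.ndarray = None    # 2x2 covariance, None for first-order

    def __post_init__(self):
        if self.nu_e < 0 or self.nu_i < 0:
            raise ValueError("rates must be nonnegative")
        if self.c is not None:
            c = np.asarray(self.c, float)
            if c.shape != (2, 2) or not np.allclose(c, c.T):
                raise ValueError("covariance must be a symmetric 2x2 matrix")
            if c[0, 0] < 0 or c[1, 1] < 0:
                raise ValueError("covariance diagonal must be nonnegative")
            self.c = c


@dataclass
class MeanFieldTrajectory:
    """Recorded state time series (Hz / pA / Hz^2), sampled every ``dt_rec`` ms."""

    t: np.ndarray
    nu_e: np.ndarray
    nu_i: np.ndarray
    W: np.ndarray
    drive: np.ndarray
    c_ee: np.ndarray = None
    c_ei: np.ndarray = None
    c_ii: np.ndarray = None

    @property
    def dt_rec(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0

    def to_csv(self, path) -> None:
        import pandas as pd
        cols = {"t_ms": self.t, "nu_e_hz": self.nu_e, "nu_i_hz": self.nu_i,
                "W_pA": self.W, "drive_hz": self.drive}
        if self.c_ee is not None:
            cols.update(c_ee=self.c_ee, c_ei=self.c_ei, c_ii=self.c_ii)
        pd.DataFrame(cols).to_csv(path, index=False)


def _unpack(params: MeanFieldParams):
    params = params.with_tfs()
    tfe, tfi = params.tf_e, params.tf_i
    return params, tfe.P, tfi.P, tfe.cfg, tfi.cfg


def simulate_first_order(params: MeanFieldParams, duration: float,
                         dt: float = 0.1, seed: int = 0,
                         init: MeanFieldState | None = None,
                         record_dt: float = 1.0) -> MeanFieldTrajectory:
    """Integrate the first-order model with Heun's method.

    Rates in/out are Hz.  Raises FloatingPointError on numerical blowup.
    """
    params, Pe, Pi, cfg_e, cfg_i = _unpack(params)
    if dt > params.T / 10:
        raise ValueError("dt must be <= T/10")
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(record_dt / dt)))
    n_rec = (n_steps + stride - 1) // stride
    out = np.empty((n_rec, 4))
    if init is None:
        init = MeanFieldState(0.5, 1.0, 0.0)
    adex = params.adex
    status = K.sim_region_first(
        n_steps, dt, params.T, Pe, Pi, cfg_e, cfg_i,
        adex.b, adex.a, adex.u_w,
        params.drive.mean * 1e-3, params.drive.sd * 1e-3, params.drive.tau,
        params.nu_aff * 1e-3, 1.0 if params.drive_symmetric else 0.0,
        init.nu_e * 1e-3, init.nu_i * 1e-3, init.W,
        int(seed) % (2**31 - 1), stride, out)
    if status != 0:
        raise FloatingPointError("mean-field integration produced non-finite state")
    t = np.arange(n_rec) * stride * dt
    return MeanFieldTrajectory(t=t, nu_e=out[:, 0] * 1e3, nu_i=out[:, 1] * 1e3,
                               W=out[:, 2], drive=out[:, 3] * 1e3)


def simulate_second_order(params: MeanFieldParams, duration: float,
                          dt: float = 0.1, seed: int = 0,
                          init: MeanFieldState | None = None,
                          record_dt: float = 1.0) -> MeanFieldTrajectory:
    """Integrate the second-order Master Equation (rates + covariances).

    TF derivatives are estimated by central finite differences.  The
    covariance is kept symmetric by construction (only c_ee, c_ei, c_ii are
    integrated); an asymmetric initial covariance is rejected.
    """
    params, Pe, Pi, cfg_e, cfg_i = _unpack(params)
    if dt > params.T / 10:
        raise ValueError("dt must be <= T/10")
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(record_dt / dt)))
    n_rec = (n_steps + stride - 1) // stride
    out = np.empty((n_rec, 7))
    if init is None:
        init = MeanFieldState(0.5, 1.0, 0.0, np.zeros((2, 2)))
    c0 = init.c if init.c is not None else np.zeros((2, 2))
    adex = params.adex
    status = K.sim_region_second(
        n_steps, dt, params.T, Pe, Pi, cfg_e, cfg_i,
        adex.b, adex.a, adex.u_w, params.N_e, params.N_i,
        params.drive.mean * 1e-3, params.drive.sd * 1e-3, params.drive.tau,
        params.nu_aff * 1e-3, 1.0 if params.drive_symmetric else 0.0,
        init.nu_e * 1e-3, init.nu_i * 1e-3, init.W,
        c0[0, 0] * 1e-6, c0[0, 1] * 1e-6, c0[1, 1] * 1e-6,
        int(seed) % (2**31 - 1), stride, _FD_H, out)
    if status != 0:
        raise FloatingPointError("mean-field integration produced non-finite state")
    t = np.arange(n_rec) * stride * dt
    return MeanFieldTrajectory(
        t=t, nu_e=out[:, 0] * 1e3, nu_i=out[:, 1] * 1e3, W=out[:, 2],
        drive=out[:, 6] * 1e3,
        c_ee=out[:, 3] * 1e6, c_ei=out[:, 4] * 1e6, c_ii=out[:, 5] * 1e6)


def _nu_i_star(params, Pe, Pi, cfg_e, cfg_i, nu_e_khz: float) -> float:
    """Inner self-consistency: smallest root of nu_i = F_i(nu_e, nu_i), kHz."""
    from scipy.optimize import brentq

    def g(ni):
        return K.tf_rate(nu_e_khz, ni, 0.0, Pi, cfg_i) - ni

    grid = np.linspace(0.0, 0.2, 401)
    vals = np.array([g(x) for x in grid])
    for lo, hi, vlo, vhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if vlo == 0.0:
            return lo
        if vlo * vhi < 0:
            return brentq(g, lo, hi, xtol=1e-12)
    return 0.0 if abs(g(0.0)) < 1e-12 else grid[int(np.argmin(np.abs(vals)))]


def find_fixed_points(params: MeanFieldParams, W_mode: str = "frozen",
                      W_value: float = 0.0, nu_max: float = 50.0,
                      scan_dnu: float = 0.1, include_zero: bool = False) -> list:
    """Fixed points of the deterministic rate map (Hz).

    For each nu_e on a scan grid the inhibitory rate is solved
    self-consistently (nu_i = F_i), then identity crossings of
    nu_e -> F_e(nu_e, nu_i*(nu_e)) are located by sign change and refined by
    bisection.  W_mode 'frozen' evaluates at W = W_value; 'self-consistent'
    uses the stationary adaptation W*(nu_e) = u_w (b nu_e + a (mu_V - E_L)).

    The default search bracket (0, 50] Hz covers the transfer function's
    calibrated domain; it can be widened up to 200 Hz (= 1/T_refr), though
    crossings beyond the fitted grid reflect polynomial extrapolation.
    Returns a list of dicts {nu_e, nu_i, W, stable} sorted by nu_e; empty if
    no crossing lies in the bracket.  ``include_zero`` additionally reports
    the boundary equilibrium at nu_e = 0 when it is self-consistent
    (F_e(0, nu_i*(0)) = 0), e.g. for an identically-zero transfer function;
    identity *crossings* never include the origin.
    """
    if W_mode not in ("frozen", "self-consistent"):
        raise ValueError("W_mode must be 'frozen' or 'self-consistent'")
    params, Pe, Pi, cfg_e, cfg_i = _unpack(params)
    adex = params.adex

    def W_of(ne_khz, ni_khz):
        if W_mode == "frozen":
            return W_value
        # stationary W; with a != 0 this is itself implicit, one fixed-point pass
        W = adex.u_w * adex.b * ne_khz
        if adex.a != 0.0:
            for _ in range(50):
                W_new = adex.u_w * (adex.b * ne_khz
                                    + adex.a * (K.mu_v(ne_khz, ni_khz, W, cfg_e)
                                                - adex.E_L_e))
                if abs(W_new - W) < 1e-10:
                    break
                W = W_new
        return W

    def h(ne_khz):
        ni = _nu_i_star(params, Pe, Pi, cfg_e, cfg_i, ne_khz)
        W = W_of(ne_khz, ni)
        return K.tf_rate(ne_khz, ni, W, Pe, cfg_e) - ne_khz, ni, W

    grid = np.arange(scan_dnu, nu_max + scan_dnu / 2, scan_dnu) * 1e-3
    vals = np.array([h(x)[0] for x in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
            lo, hi = grid[i], grid[i + 1]
            flo = vals[i]
            for _ in range(60):     # bisection on the (non-smooth-safe) map
                mid = 0.5 * (lo + hi)
                fm = h(mid)[0]
                if flo * fm <= 0:
                    hi = mid
                else:
                    lo, flo = mid, fm
            ne = 0.5 * (lo + hi)
            _, ni, W = h(ne)
            stable = vals[i] > 0 and vals[i + 1] < 0    # map crosses identity downward
            roots.append({"nu_e": ne * 1e3, "nu_i": ni * 1e3, "W": W,
                          "stable": bool(stable)})
    # merge near-duplicates from grid-edge hits
    merged = []
    for r in roots:
        if merged and abs(r["nu_e"] - merged[-1]["nu_e"]) < scan_dnu:
            continue
        merged.append(r)
    if include_zero:
        h0, ni0, W0 = h(0.0)
        if abs(h0) < 1e-9:
            stable0 = vals[0] < 0      # flow toward zero just above it
            merged.insert(0, {"nu_e": 0.0, "nu_i": ni0 * 1e3, "W": W0,
                              "stable": bool(stable0)})
    return merged
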