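"""Parameter grid exploration of the whole-brain model.

Scans any subset of (S, E_L_e, E_L_i, T, b_e) over their physiological
ranges, runs a short whole-brain simulation per configuration, and extracts
summary features (rate means/SDs, mean functional connectivity, regime
label).  The full-resolution scan of all five axes at 16 values each is a
cluster-scale undertaking; this driver runs arbitrary sub-grids serially or
with joblib workers and is deterministic for a fixed master seed and grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .analysis import fc_pearson
from .adex_network import classify_state
from .brain_network import BrainSimConfig, simulate_brain

__all__ = ["ScanSpec", "run_scan", "PARAM_RANGES"]

#: physiological ranges of the scanned parameters
PARAM_RANGES: Dict[str, tuple] = {
    "S": (0.0, 0.5),            # coupling strength, dimensionless
    "E_L_e": (-80.0, -60.0),    # mV
    "E_L_i": (-80.0, -60.0),    # mV
    "T": (5.0, 40.0),           # ms
    "b_e": (0.0, 120.0),        # pA
}


@dataclass
class ScanSpec:
    """Grid specification: parameter name -> explicit values or n_values
    evenly spaced over the full range (default 16)."""

    values: Dict[str, Sequence[float]] = field(default_factory=dict)
    n_values: int = 16
    duration: float = 7_000.0       # ms per configuration
    transient: float = 2_000.0      # ms discarded before feature extraction
    seed: int = 0

    def __post_init__(self):
        if self.n_values < 2:
            raise ValueError("n_values must be >= 2")
        for name, vals in self.values.items():
            if name not in PARAM_RANGES:
                raise ValueError(f"unknown scan parameter {name!r}")
            lo, hi = PARAM_RANGES[name]
            vals = np.asarray(vals, float)
            if vals.min() < lo or vals.max() > hi:
                raise ValueError(
                    f"{name} values outside physiological range [{lo}, {hi}]")
            self.values[name] = vals

    def axis(self, name: str) -> np.ndarray:
        if name in self.values:
            return np.asarray(self.values[name], float)
        lo, hi = PARAM_RANGES[name]
        return np.linspace(lo, hi, self.n_values)

    def grid(self) -> pd.DataFrame:
        """Cartesian product of the requested axes (unrequested parameters
        stay at their model defaults)."""
        names = list(self.values.keys())
        mesh = np.meshgrid(*[self.axis(n) for n in names], indexing="ij")
        return pd.DataFrame({n: m.ravel() for n, m in zip(names, mesh)})


def _run_one(config: BrainSimConfig, row: dict, transient: float,
             seed: int) -> dict:
    mf = config.mf
    adex = mf.adex
    if "b_e" in row:
        adex = adex.replace(b=float(row["b_e"]))
    if "E_L_e" in row:
        adex = adex.replace(E_L_e=float(row["E_L_e"]))
    if "E_L_i" in row:
        adex = adex.replace(E_L_i=float(row["E_L_i"]))
    mf = replace(mf, adex=adex)
    if "T" in row:
        mf = replace(mf, T=float(row["T"]))
    cfg = replace(config, mf=mf, transient=transient, seed=seed)
    if "S" in row:
        cfg = replace(cfg, S=float(row["S"]))
    out = dict(row)
    try:
        ts = simulate_brain(cfg).post_transient()
        gm = ts.nu_e.mean(axis=0)
        st = classify_state(gm, bin=ts.dt, transient=0.0)
        fc = fc_pearson(ts)
        out.update(
            mean_nu_e=float(ts.nu_e.mean()), sd_nu_e=float(gm.std()),
            mean_nu_i=float(ts.nu_i.mean()),
            sd_nu_i=float(ts.nu_i.mean(axis=0).std()),
            mean_fc=fc.mean_offdiag(), state=st["label"],
            silent_fraction=st["silent_fraction"], failed=False)
    except (FloatingPointError, ValueError) as exc:   # record, keep scanning
        out.update(mean_nu_e=np.nan, sd_nu_e=np.nan, mean_nu_i=np.nan,
                   sd_nu_i=np.nan, mean_fc=np.nan, state="failed",
                   silent_fraction=np.nan, failed=True, error=str(exc))
    return out


def run_scan(spec: ScanSpec, config: BrainSimConfig,
             workers: int = 1) -> pd.DataFrame:
    """Run the grid; one row of features per configuration.

    Per-configuration seeds are derived deterministically from the spec seed
    and the row index, so the table is reproducible for any worker count.
    Individual failures are recorded in the ``failed``/``error`` columns.
    """
    grid = spec.grid()
    rows = grid.to_dict("records")
    seeds = [int(np.random.SeedSequence([spec.seed, i]).generate_state(1)[0]
                 % (2**31 - 1)) for i in range(len(rows))]
    spec_dur = replace(config, duration=spec.duration)
    if workers > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=workers)(
            delayed(_run_one)(spec_dur, row, spec.transient, sd)
            for row, sd in zip(rows, seeds))
    else:
        results = [_run_one(spec_dur, row, spec.transient, sd)
                   for row, sd in zip(rows, seeds)]
    return pd.DataFrame(results)
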