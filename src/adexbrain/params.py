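"""Parameter containers for the AdEx single-neuron model and its mean-field reduction.

Units follow the convention used throughout the package: time in ms, voltage in mV,
conductance in nS, capacitance in pF, current in pA.  Firing rates are stored in kHz
(1/ms) internally; every public interface takes and returns Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["AdExParams", "OUDriveSpec", "MeanFieldParams", "RS_FS_DEFAULTS"]


@dataclass
class AdExParams:
    """Constants of the adaptive exponential integrate-and-fire neuron with
    conductance-based synapses.

    The defaults describe the two-population cortical circuit used throughout:
    regular-spiking (RS) excitatory cells carrying spike-frequency adaptation ``b``
    and fast-spiking (FS) inhibitory cells without adaptation.  Population-specific
    values carry ``_e`` / ``_i`` suffixes.
    """

    c_m: float = 200.0          # membrane capacitance, pF
    g_L: float = 10.0           # leak conductance, nS
    E_L_e: float = -63.0        # RS leak reversal, mV
    E_L_i: float = -65.0        # FS leak reversal, mV
    Delta_e: float = 2.0        # RS spike sharpness, mV
    Delta_i: float = 0.5        # FS spike sharpness, mV
    v_thr: float = -50.0        # exponential-term threshold, mV
    v_peak_e: float = -40.0     # RS spike-detection voltage, mV
    v_peak_i: float = -47.5     # FS spike-detection voltage, mV
    v_reset: float = -65.0      # reset voltage, mV
    T_refr: float = 5.0         # refractory period, ms
    a: float = 0.0              # subthreshold adaptation, nS (RS only)
    b: float = 0.0              # spike-triggered adaptation, pA (RS only)
    u_w: float = 500.0          # adaptation time constant, ms
    Q_e: float = 1.5            # excitatory quantal conductance, nS
    Q_i: float = 5.0            # inhibitory quantal conductance, nS
    E_e: float = 0.0            # excitatory synaptic reversal, mV
    E_i: float = -80.0          # inhibitory synaptic reversal, mV
    u_e: float = 5.0            # excitatory synaptic decay, ms
    u_i: float = 5.0            # inhibitory synaptic decay, ms

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError("c_m must be positive")
        if self.g_L <= 0:
            raise ValueError("g_L must be positive")
        if self.u_w <= 0 or self.u_e <= 0 or self.u_i <= 0:
            raise ValueError("time constants u_w, u_e, u_i must be positive")
        for EL in (self.E_L_e, self.E_L_i):
            if not (self.E_i < EL < self.v_thr):
                raise ValueError("require E_i < E_L < v_thr")
        if not (self.v_thr < self.v_peak_e and self.v_thr < self.v_peak_i):
            raise ValueError("require v_thr < v_peak")

    # population views --------------------------------------------------

    def E_L(self, population: str) -> float:
        return self.E_L_e if population == "e" else self.E_L_i

    def Delta(self, population: str) -> float:
        return self.Delta_e if population == "e" else self.Delta_i

    def v_peak(self, population: str) -> float:
        return self.v_peak_e if population == "e" else self.v_peak_i

    def replace(self, **kw) -> "AdExParams":
        return replace(self, **kw)


# canonical RS (adapting excitatory) / FS (non-adapting inhibitory) pairing
RS_FS_DEFAULTS = AdExParams()


@dataclass
class OUDriveSpec:
    """Ornstein-Uhlenbeck afferent-rate drive (Hz at the interface).

    The drive models background synaptic bombardment; it is added to the
    excitatory input-rate argument of the transfer function, never to the state.
    """

    mean: float = 0.4       # Hz
    sd: float = 0.1         # Hz (stationary standard deviation)
    tau: float = 5.0        # correlation time, ms

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("drive SD must be nonnegative")
        if self.tau <= 0:
            raise ValueError("drive correlation time must be positive")


@dataclass
class MeanFieldParams:
    """Parameters of the two-population mean-field with adaptation.

    ``T`` is the population (Markov) timescale of the rate equations; ``N_e``/``N_i``
    enter the covariance source term of the second-order model.  Transfer functions
    ``tf_e``/``tf_i`` are fitted :class:`~adexbrain.transfer_function.TransferFunction`
    objects (populated lazily from the packaged defaults when left as None).
    """

    T: float = 25.0
    N_e: int = 8000
    N_i: int = 2000
    adex: AdExParams = field(default_factory=AdExParams)
    drive: OUDriveSpec = field(default_factory=OUDriveSpec)
    nu_aff: float = 0.0     # afferent (thalamic) rate, Hz
    #: whether the OU drive also enters the inhibitory transfer-function input
    #: (the network-level convention); False restricts it to the excitatory one
    drive_symmetric: bool = True
    tf_e: Optional[object] = None
    tf_i: Optional[object] = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.N_e <= 0 or self.N_i <= 0:
            raise ValueError("population sizes must be positive")

    def with_tfs(self) -> "MeanFieldParams":
        """Return a copy with transfer functions filled in from the packaged fit
        if they were not supplied."""
        if self.tf_e is not None and self.tf_i is not None:
            return self
        from .transfer_function import default_transfer_functions

        tf_e, tf_i = default_transfer_functions()
        return replace(self, tf_e=self.tf_e or tf_e, tf_i=self.tf_i or tf_i)


def rng_from_seed(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic splittable RNG: a master seed plus a stream tag tuple."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))
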