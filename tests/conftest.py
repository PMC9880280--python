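"""Shared fixtures.

The expensive simulations (5-s spiking runs, 12-s whole-brain runs, the PCI
trial ensembles) are session-scoped and lazily built, so the regime tests and
the acceptance tests reuse the same data.
"""

import numpy as np
import pytest

from adexbrain import (AdExParams, BrainSimConfig, MeanFieldParams,
                       build_network, generate_synthetic, shuffle_weights,
                       simulate_brain, simulate_first_order, simulate_spiking)

SPIKING_SEEDS = (2, 3, 4)


@pytest.fixture(scope="session")
def arch10k():
    return build_network(10_000, p=0.05, frac_inh=0.2, seed=1)


@pytest.fixture(scope="session")
def arch_small():
    """2000-neuron network for fast dynamical unit tests."""
    return build_network(2_000, p=0.05, frac_inh=0.2, seed=1)


@pytest.fixture(scope="session")
def spiking_runs(arch10k):
    """Default-condition 5-s spiking runs: {(b, seed): SpikeData}."""
    runs = {}
    for b in (0.0, 60.0):
        for seed in SPIKING_SEEDS:
            runs[(b, seed)] = simulate_spiking(
                arch10k, AdExParams(b=b), duration=5_000.0, seed=seed)
    return runs


@pytest.fixture(scope="session")
def conn68():
    return generate_synthetic(68, seed=5)


@pytest.fixture(scope="session")
def brain_runs(conn68):
    """12-s whole-brain runs at default coupling: {b: post-transient series}."""
    out = {}
    for b in (0.0, 60.0):
        cfg = BrainSimConfig(connectome=conn68,
                             mf=MeanFieldParams(adex=AdExParams(b=b)),
                             duration=12_000.0, seed=7)
        out[b] = simulate_brain(cfg).post_transient()
    return out


@pytest.fixture(scope="session")
def brain_runs_shuffled(conn68):
    sh = shuffle_weights(conn68, seed=11)
    out = {}
    for b in (0.0, 60.0):
        cfg = BrainSimConfig(connectome=sh,
                             mf=MeanFieldParams(adex=AdExParams(b=b)),
                             duration=12_000.0, seed=7)
        out[b] = simulate_brain(cfg).post_transient()
    return out


@pytest.fixture(scope="session")
def mf_runs():
    """10-s first-order mean-field runs: {b: trajectory}."""
    return {b: simulate_first_order(MeanFieldParams(adex=AdExParams(b=b)),
                                    10_000.0, seed=3)
            for b in (0.0, 60.0)}


@pytest.fixture(scope="session")
def pci_results(conn68):
    from adexbrain import pci_experiment
    cfg = BrainSimConfig(connectome=conn68, duration=3_000.0)
    return pci_experiment(cfg, b_values=(0.0, 20.0, 40.0, 60.0),
                          amplitudes=(0.1,), n_trials=40, seed=42)


def rate_of(spikes, population="e", bin=0.5):
    from adexbrain import population_rate
    return population_rate(spikes, bin=bin, population=population)[1]


# derandomized hypothesis: property tests explore the same cases every run
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
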