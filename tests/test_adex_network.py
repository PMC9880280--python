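"""Spiking-network module: wiring, integration, rates, regime classification."""

import numpy as np
import pytest
from scipy.optimize import brentq

from adexbrain import (AdExParams, SpikeData, build_network, classify_state,
                       population_rate, simulate_spiking)

from conftest import SPIKING_SEEDS, rate_of


class TestBuildNetwork:
    def test_zero_probability_gives_empty_adjacency(self):
        arch = build_network(10, p=0.0, seed=0)
        assert all(len(pre) == 0 for pre in arch.pre)

    def test_indegree_matches_binomial_moments(self, arch10k):
        """Mean in-degree ~ p(N-1) = 500 (400 exc, 100 inh), each neuron
        within 5 SD of the binomial expectation."""
        N, p = arch10k.N, arch10k.p
        deg = np.array([len(pre) for pre in arch10k.pre])
        mean, sd = p * (N - 1), np.sqrt((N - 1) * p * (1 - p))
        assert abs(deg.mean() - mean) < 5 * sd / np.sqrt(N)
        assert np.all(np.abs(deg - mean) < 5 * sd)
        exc_deg = np.array([np.sum(pre < arch10k.n_e) for pre in arch10k.pre[:200]])
        assert abs(exc_deg.mean() - p * arch10k.n_e) < 5 * np.sqrt(
            arch10k.n_e * p * (1 - p) / 200)

    def test_no_self_connections(self, arch_small):
        for i, pre in enumerate(arch_small.pre):
            assert i not in pre

    def test_same_seed_identical_adjacency(self):
        a = build_network(500, seed=9)
        b = build_network(500, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.pre, b.pre))

    @pytest.mark.parametrize("kw", [dict(N=1), dict(p=1.5), dict(p=-0.1),
                                    dict(frac_inh=0.0)])
    def test_invalid_arguments_rejected(self, kw):
        with pytest.raises(ValueError):
            build_network(**{"N": 100, "p": 0.05, "frac_inh": 0.2, **kw})


class TestSimulateSpiking:
    def test_single_neuron_without_input_stays_at_subthreshold_fixed_point(self):
        """v converges to the root of g_L(E_L - v) + g_L Delta e^{(v-v_thr)/Delta} = 0,
        which lies within 0.5 mV of E_L, and no spikes are emitted."""
        arch = build_network(2, p=0.0, seed=0)
        p = AdExParams()
        sp = simulate_spiking(arch, p, duration=1_000.0, drive_rate=0.0,
                              seed=1, monitor=np.array([0]), monitor_dt=1.0)
        assert len(sp.times) == 0
        v_end = sp.traces["v"][-1, 0]

        def f(v):
            return p.g_L * (p.E_L_e - v) + p.g_L * p.Delta_e * np.exp(
                (v - p.v_thr) / p.Delta_e)

        v_star = brentq(f, -80.0, p.v_thr)
        assert abs(v_star - p.E_L_e) < 0.5
        assert abs(v_end - v_star) < 0.05

    def test_refractory_intervals_respected(self, arch_small):
        sp = simulate_spiking(arch_small, AdExParams(b=0.0), duration=1_000.0,
                              seed=4)
        for train in sp.spike_trains():
            if len(train) > 1:
                assert np.all(np.diff(train) >= AdExParams().T_refr - 1e-9)

    def test_conductances_nonnegative(self, arch_small):
        sp = simulate_spiking(arch_small, AdExParams(b=60.0), duration=500.0,
                              seed=4, monitor=np.arange(5), monitor_dt=0.5)
        assert np.all(sp.traces["G_e"] >= 0)
        assert np.all(sp.traces["G_i"] >= 0)

    def test_seeded_determinism(self, arch_small):
        a = simulate_spiking(arch_small, AdExParams(b=0.0), duration=500.0, seed=12)
        b = simulate_spiking(arch_small, AdExParams(b=0.0), duration=500.0, seed=12)
        assert np.array_equal(a.neuron_ids, b.neuron_ids)
        assert np.array_equal(a.times, b.times)

    def test_dt_rejected_above_limit(self, arch_small):
        with pytest.raises(ValueError):
            simulate_spiking(arch_small, AdExParams(), duration=10.0, dt=0.2)

    def test_dt_halving_changes_mean_rate_below_5_percent(self, arch_small):
        rates = []
        for dt in (0.1, 0.05):
            sp = simulate_spiking(arch_small, AdExParams(b=0.0),
                                  duration=3_000.0, dt=dt, seed=6)
            r = rate_of(sp)
            rates.append(r[int(500 / 0.5):].mean())
        assert abs(rates[0] - rates[1]) / rates[1] < 0.05

    def test_tsv_hdf5_roundtrip(self, arch_small, tmp_path):
        sp = simulate_spiking(arch_small, AdExParams(), duration=200.0, seed=3)
        sp.to_tsv(tmp_path / "spk.tsv")
        sp.to_hdf5(tmp_path / "spk.h5")
        back = SpikeData.from_hdf5(tmp_path / "spk.h5")
        assert np.array_equal(back.times, sp.times)
        loaded = np.loadtxt(tmp_path / "spk.tsv", skiprows=1)
        assert loaded.shape[0] == len(sp.times)


class TestPopulationRate:
    def _spikes(self, ids, times, n_e=1, n_i=1, duration=1000.0):
        return SpikeData(n_e=n_e, n_i=n_i, duration=duration,
                         neuron_ids=np.asarray(ids), times=np.asarray(times, float))

    def test_empty_spikes_give_all_zero_series(self):
        _, r = population_rate(self._spikes([], []), bin=100.0)
        assert r.shape == (10,)
        assert np.all(r == 0)

    def test_uniform_spiking_counting_identity(self):
        """1 neuron, 10 spikes uniformly over 1 s, 100-ms bins -> 10 Hz everywhere."""
        times = 50.0 + 100.0 * np.arange(10)
        _, r = population_rate(self._spikes(np.zeros(10, int), times), bin=100.0)
        assert np.allclose(r, 10.0)

    def test_bad_bin_rejected(self):
        with pytest.raises(ValueError):
            population_rate(self._spikes([], []), bin=0.0)


class TestClassifyState:
    def test_constant_rate_is_ai(self):
        r = np.full(6000, 10.0)      # 3 s at 0.5 ms bins
        st = classify_state(r)
        assert st["label"] == "AI"
        assert st["silent_fraction"] == 0.0

    def test_square_wave_is_updown(self):
        r = np.tile(np.r_[np.zeros(1000), np.full(1000, 20.0)], 4)
        st = classify_state(r)
        assert st["label"] == "UpDown"
        assert st["silent_fraction"] > 0.3

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            classify_state(np.ones(100))


class TestRegimes:
    @pytest.mark.parametrize("seed", SPIKING_SEEDS)
    def test_adaptation_switches_ai_to_updown(self, spiking_runs, seed):
        """Changing only b flips the network between asynchronous-irregular
        and Up-Down slow waves, for every seed."""
        st0 = classify_state(rate_of(spiking_runs[(0.0, seed)]))
        st60 = classify_state(rate_of(spiking_runs[(60.0, seed)]))
        assert st0["label"] == "AI"
        assert st60["label"] == "UpDown"

    def test_updown_rate_distribution_is_bimodal(self, spiking_runs):
        """b=60: 20-ms block rates separate into near-silent and active modes."""
        r = rate_of(spiking_runs[(60.0, 2)])[1000:]
        blocks = r[:len(r) // 40 * 40].reshape(-1, 40).mean(axis=1)
        assert np.mean(blocks < 0.5) > 0.1      # Down mode
        assert np.mean(blocks > 2.0) > 0.05     # Up mode
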