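"""Mean-field module: integrators, fixed points, regimes."""

import numpy as np
import pytest
from scipy.signal import welch

from adexbrain import (AdExParams, MeanFieldParams, MeanFieldState,
                       find_fixed_points, simulate_first_order,
                       simulate_second_order)
from adexbrain.transfer_function import TransferFunction


def _silent_tf(population):
    """A transfer function that is numerically zero everywhere in the
    operating range (effective threshold far above any reachable mu_V)."""
    P = np.zeros(10)
    P[0] = 100.0
    return TransferFunction(population=population, P=P)


class TestFirstOrder:
    def test_seeded_determinism_of_ou_paths(self):
        mfp = MeanFieldParams(adex=AdExParams(b=0.0))
        a = simulate_first_order(mfp, 1_000.0, seed=5)
        b = simulate_first_order(mfp, 1_000.0, seed=5)
        assert np.array_equal(a.nu_e, b.nu_e)
        assert np.array_equal(a.drive, b.drive)

    def test_rates_stay_in_physical_bounds(self, mf_runs):
        for tr in mf_runs.values():
            assert np.all(tr.nu_e >= 0) and np.all(tr.nu_e <= 200)
            assert np.all(tr.nu_i >= 0) and np.all(tr.nu_i <= 200)

    def test_w_nonnegative_without_subthreshold_adaptation(self, mf_runs):
        assert np.all(mf_runs[60.0].W >= -1e-9)

    def test_b0_fluctuates_around_nonzero_fixed_point(self, mf_runs):
        x = mf_runs[0.0].nu_e[2000:]
        fps = find_fixed_points(MeanFieldParams(adex=AdExParams(b=0.0)))
        high = max(f["nu_e"] for f in fps if f["stable"])
        assert x.min() > 1.0                      # never collapses
        assert abs(x.mean() - high) / high < 0.5  # hovers near the attractor

    def test_b60_alternates_between_high_and_silent(self, mf_runs):
        x = mf_runs[60.0].nu_e[2000:]
        assert np.mean(x < 1.0) > 0.3             # Down states
        assert x.max() > 10.0                     # Up states

    def test_zero_noise_at_fixed_point_stays_stationary(self):
        mfp = MeanFieldParams(adex=AdExParams(b=0.0))
        mfp.drive.sd = 0.0
        mfp.drive.mean = 0.0
        fps = find_fixed_points(mfp)
        high = [f for f in fps if f["stable"]][-1]
        tr = simulate_first_order(
            mfp, 2_000.0, seed=0,
            init=MeanFieldState(high["nu_e"], high["nu_i"], 0.0))
        assert abs(tr.nu_e[-1] - high["nu_e"]) < 0.1
        assert abs(tr.nu_i[-1] - high["nu_i"]) < 0.5

    def test_dt_too_large_rejected(self):
        with pytest.raises(ValueError):
            simulate_first_order(MeanFieldParams(T=5.0), 100.0, dt=1.0)

    def test_slow_wave_frequency_decreases_with_uw(self):
        """Doubling the adaptation time constant slows the Up-Down rhythm."""
        peaks = []
        for uw in (250.0, 500.0, 1000.0):
            mfp = MeanFieldParams(adex=AdExParams(b=60.0, u_w=uw))
            tr = simulate_first_order(mfp, 12_000.0, seed=3)
            x = tr.nu_e[2000:]
            f, P = welch(x - x.mean(), fs=1000.0, nperseg=8192)
            sel = (f >= 0.1) & (f <= 20.0)
            peaks.append(f[sel][np.argmax(P[sel])])
        assert peaks[0] > peaks[1] > peaks[2]


class TestSecondOrder:
    def test_large_n_limit_converges_to_first_order(self):
        """The finite-size covariance source scales as 1/N: started at the
        deterministic fixed point without drive noise, the N -> infinity
        second-order trajectory coincides with the first-order one (c stays
        at zero), and the stationary covariance shrinks with N."""
        from adexbrain.params import OUDriveSpec

        quiet = OUDriveSpec(mean=0.0, sd=0.0, tau=5.0)
        mfp = MeanFieldParams(adex=AdExParams(b=0.0), drive=quiet)
        fp = [f for f in find_fixed_points(mfp) if f["stable"]][-1]
        init = MeanFieldState(fp["nu_e"], fp["nu_i"], 0.0, np.zeros((2, 2)))
        tr1 = simulate_first_order(mfp, 1_000.0, seed=4, init=init)
        mfp_inf = MeanFieldParams(N_e=10**9, N_i=10**9,
                                  adex=AdExParams(b=0.0), drive=quiet)
        tr2 = simulate_second_order(mfp_inf, 1_000.0, seed=4, init=init)
        assert np.max(np.abs(tr1.nu_e - tr2.nu_e)) < 0.05
        assert tr2.c_ee[-1] < 1e-4

        # same setup at the default size: source term visible, c_ee > 0
        mfp_fin = MeanFieldParams(adex=AdExParams(b=0.0), drive=quiet)
        tr3 = simulate_second_order(mfp_fin, 1_000.0, seed=4, init=init)
        assert tr3.c_ee[-1] > 1e3 * max(tr2.c_ee[-1], 1e-12)

    def test_asymmetric_initial_covariance_rejected(self):
        with pytest.raises(ValueError):
            MeanFieldState(1.0, 1.0, 0.0, np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_covariance_diagonal_nonnegative_and_finite(self):
        mfp = MeanFieldParams(adex=AdExParams(b=0.0))
        tr = simulate_second_order(mfp, 2_000.0, seed=4)
        assert np.all(tr.c_ee >= 0) and np.all(tr.c_ii >= 0)
        assert np.all(np.isfinite(tr.c_ei))


class TestFixedPoints:
    def test_silent_tf_yields_only_origin(self):
        mfp = MeanFieldParams(tf_e=_silent_tf("RS"), tf_i=_silent_tf("FS"))
        assert find_fixed_points(mfp) == []
        fps = find_fixed_points(mfp, include_zero=True)
        assert len(fps) == 1
        assert fps[0]["nu_e"] == 0.0 and fps[0]["nu_i"] == pytest.approx(0.0)

    def test_b0_defaults_have_two_identity_crossings(self):
        fps = find_fixed_points(MeanFieldParams(adex=AdExParams(b=0.0)))
        assert len(fps) == 2
        low, high = fps
        assert low["nu_e"] < 1.0 and not low["stable"]
        assert high["nu_e"] > 3.0 and high["stable"]

    def test_crossings_match_brute_force_scan(self):
        """Count and locations agree with a dense direct scan at 0.01 Hz."""
        from adexbrain.mean_field import _nu_i_star, _unpack
        from adexbrain import _kernels as K

        mfp = MeanFieldParams(adex=AdExParams(b=0.0))
        fps = find_fixed_points(mfp)
        params, Pe, Pi, cfg_e, cfg_i = _unpack(mfp)
        grid = np.arange(0.01, 50.0, 0.01) * 1e-3
        h = np.array([K.tf_rate(x, _nu_i_star(params, Pe, Pi, cfg_e, cfg_i, x),
                                0.0, Pe, cfg_e) - x for x in grid])
        crossings = grid[:-1][np.diff(np.sign(h)) != 0] * 1e3
        assert len(crossings) == len(fps)
        for c, f in zip(crossings, fps):
            assert abs(c - f["nu_e"]) < 0.02

    def test_invalid_w_mode_rejected(self):
        with pytest.raises(ValueError):
            find_fixed_points(MeanFieldParams(), W_mode="bogus")


class TestCrossScale:
    def test_first_order_mean_matches_spiking_network(self, mf_runs, spiking_runs):
        """Stationary wake-state excitatory rate of the mean-field within 20%
        of the spiking network's."""
        from conftest import rate_of
        mf_mean = mf_runs[0.0].nu_e[2000:].mean()
        spk = rate_of(spiking_runs[(0.0, 2)])
        spk_mean = spk[1000:].mean()
        assert abs(mf_mean - spk_mean) / spk_mean < 0.2
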