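"""Analysis metrics: PSTH, Gaussian rates, sustainedness, IPSP detection,
dynamic-range slopes, KC-GGN locality correlation, result-file round trip."""

import numpy as np
import pytest

from mbsim.analysis import (detect_ipsps, dynamic_range_slope, gaussian_rate,
                            kc_ggn_local_correlation, population_psth,
                            sustainedness_index, synchrony_index)
from mbsim.io import SimulationResult, load_result, save_result
from mbsim.synapses import SpikeSynapseParams, spike_conductance


class TestPSTH:
    def test_empty_raster(self):
        _, counts = population_psth(np.empty(0), 100.0, (0.0, 1000.0))
        assert counts.sum() == 0

    def test_single_synchronous_bin(self):
        spikes = np.full(100, 550.0)
        _, counts = population_psth(spikes, 100.0, (0.0, 1000.0))
        assert counts.max() == 100
        assert counts.sum() == 100

    def test_total_count_conserved(self):
        rng = np.random.default_rng(0)
        spikes = rng.uniform(0, 999.9, size=777)
        _, counts = population_psth(spikes, 37.0, (0.0, 1000.0))
        assert counts.sum() == 777


class TestGaussianRate:
    def test_peak_height_closed_form(self):
        t = np.linspace(0, 1000, 20001)
        rate = gaussian_rate(np.array([500.0]), 100.0, t)
        assert rate.max() == pytest.approx(1.0 / (100.0 * np.sqrt(2 * np.pi)),
                                           rel=1e-6)
        assert t[np.argmax(rate)] == pytest.approx(500.0, abs=0.1)

    def test_integral_equals_spike_count(self):
        t = np.linspace(-500, 1500, 40001)
        rate = gaussian_rate(np.array([200.0, 700.0, 710.0]), 50.0, t)
        assert np.trapezoid(rate, t) == pytest.approx(3.0, rel=1e-4)

    def test_no_spikes_zero(self):
        t = np.linspace(0, 100, 101)
        assert not gaussian_rate(np.empty(0), 10.0, t).any()


class TestSustainedness:
    def test_flat_trace_scores_zero(self):
        t = np.arange(0, 2000.0, 1.0)
        vm = np.full_like(t, -51.0)
        assert sustainedness_index(t, vm, (1000.0, 2000.0)) == 0.0

    def test_constant_depolarization_scores_one(self):
        t = np.arange(0, 2000.0, 1.0)
        vm = np.where(t >= 1000.0, -46.0, -51.0)
        assert sustainedness_index(t, vm, (1000.0, 2000.0)) == 1.0

    def test_single_peak_scores_one_tenth(self):
        t = np.arange(0, 2000.0, 1.0)
        vm = np.full_like(t, -51.0)
        vm[(t >= 1400) & (t < 1500)] = -44.0
        assert sustainedness_index(t, vm, (1000.0, 2000.0)) == pytest.approx(0.1)

    def test_synchrony_index_extremes(self):
        sync = np.full(60, 505.0)
        spread = np.linspace(0, 999, 60)
        assert synchrony_index(sync, (0.0, 1000.0)) == 1.0
        assert synchrony_index(spread, (0.0, 1000.0)) < 0.15
        assert synchrony_index(np.empty(0), (0.0, 1000.0)) == 0.0


class TestIPSPDetection:
    def test_injected_ipsps_recovered(self):
        """Ground-truth oracle: rest + double-exponential IPSPs at known
        times must be recalled >= 95% with < 5 ms timing error."""
        rng = np.random.default_rng(8)
        dt = 0.5
        dur = 20_000.0
        t = np.arange(0, dur, dt)
        true_times = np.sort(rng.uniform(500, dur - 500, size=60))
        # enforce separation > refractory
        true_times = true_times[np.concatenate(
            [[True], np.diff(true_times) > 40.0])]
        p = SpikeSynapseParams(weight=1.0, tau_rise=2.0, tau_decay=12.0)
        vm = -51.0 - 1.5 * spike_conductance(true_times, p, dt, dur)
        vm += rng.normal(scale=0.03, size=len(vm))
        detected = detect_ipsps(t, vm, min_amplitude=0.5, refractory=20.0)
        # match each true event to the nearest detection
        hits = 0
        for ts in true_times:
            err = np.min(np.abs(detected - (ts + 7.0)))  # ~peak lag of kernel
            if err < 5.0:
                hits += 1
        assert hits / len(true_times) >= 0.95

    def test_flat_trace_yields_none(self):
        t = np.arange(0, 5000.0, 0.5)
        vm = np.full_like(t, -51.0)
        assert len(detect_ipsps(t, vm)) == 0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_ipsps(np.array([0.0, 1.0]), np.array([-51.0, -51.0]))


class TestSlope:
    def test_identical_curves_ratio_one(self):
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        c = np.array([0, 10, 20, 30, 40])
        ref = dynamic_range_slope(a, c)
        assert dynamic_range_slope(a, c, ref_slope=ref) == pytest.approx(1.0)

    def test_doubled_counts_ratio_two(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        c = np.array([0, 5, 10, 15])
        ref = dynamic_range_slope(a, c)
        assert dynamic_range_slope(a, 2 * c, ref_slope=ref) == pytest.approx(2.0)

    def test_too_few_rising_points_flagged(self):
        with pytest.raises(ValueError):
            dynamic_range_slope(np.array([0.1, 0.2, 0.3]),
                                np.array([0, 5, 2]))


class TestLocalCorrelation:
    def test_shuffled_assignment_uncorrelated(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, size=2000).astype(float)
        dv = rng.normal(5, 1, size=2000)
        r = kc_ggn_local_correlation(counts, dv)
        assert abs(r) < 0.08

    def test_negative_coupling_detected(self):
        rng = np.random.default_rng(2)
        dv = rng.normal(5, 1, size=500)
        counts = 20 - 3 * dv + rng.normal(scale=0.5, size=500)
        assert kc_ggn_local_correlation(counts, dv) < -0.9

    def test_degenerate_input_flagged(self):
        with pytest.raises(ValueError):
            kc_ggn_local_correlation(np.ones(50), np.ones(50))
        with pytest.raises(ValueError):
            kc_ggn_local_correlation(np.ones(5), np.ones(5))


class TestResultFile:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        res = SimulationResult(
            t=np.arange(0.0, 100.0, 0.5),
            ggn_vm=rng.normal(-51, 1, 200),
            kc_spikes=[np.sort(rng.uniform(0, 100, rng.integers(0, 5)))
                       for _ in range(20)],
            ig_vm=rng.normal(-65, 2, 200),
            comp_mean_dv=rng.normal(size=30),
            kc_mean_v=rng.normal(-60, 1, 20),
            config={"n_kc": 20}, seed=7,
        )
        path = tmp_path / "res.h5"
        save_result(res, path)
        back = load_result(path)
        np.testing.assert_array_equal(back.ggn_vm, res.ggn_vm)
        np.testing.assert_array_equal(back.ig_vm, res.ig_vm)
        assert back.n_kc == res.n_kc
        for a, b in zip(back.kc_spikes, res.kc_spikes):
            np.testing.assert_array_equal(a, b)
        assert back.config == res.config and back.seed == 7
        # write -> read -> write produces identical payloads
        path2 = tmp_path / "res2.h5"
        save_result(back, path2)
        back2 = load_result(path2)
        np.testing.assert_array_equal(back2.ggn_vm, res.ggn_vm)
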