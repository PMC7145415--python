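"""PN population activity: class bookkeeping, rate recovery, the shifting
excitation/inhibition scheme, and Poisson sampling properties."""

import numpy as np
import pytest

from mbsim.analysis import population_psth
from mbsim.pn_model import (CLASS_EXCITED, CLASS_INHIBITED, CLASS_SHIFTING,
                            CLASS_SPONTANEOUS, GROUP_PATTERNS,
                            PNPopulationConfig, rates_fixed, rates_shifting,
                            sample_poisson)


class TestFixedScheme:
    def test_population_counts_at_830(self):
        counts = PNPopulationConfig(n_pn=830).counts
        assert counts["spontaneous"] == 639   # round(0.77 * 830)
        assert counts["excited"] == 166       # round(0.20 * 830)
        assert counts["inhibited"] == 64      # round(0.10 * 639)

    def test_excited_rate_outside_odor_is_spontaneous(self):
        cfg = PNPopulationConfig(odor_window=(1.0, 2.0))
        r = rates_fixed(cfg, 0)
        i = int(np.flatnonzero(r.response_class == CLASS_EXCITED)[0])
        assert r.rate(i, np.array([0.5]))[0] == pytest.approx(2.6)
        assert r.rate(i, np.array([2.5]))[0] == pytest.approx(2.6)

    def test_inhibited_silent_during_odor(self):
        cfg = PNPopulationConfig(odor_window=(1.0, 2.0))
        r = rates_fixed(cfg, 0)
        i = int(np.flatnonzero(r.response_class == CLASS_INHIBITED)[0])
        assert r.rate(i, np.array([1.5]))[0] == 0.0
        assert r.rate(i, np.array([2.2]))[0] == pytest.approx(2.6)

    def test_modulated_rate_averages_to_odor_rate(self):
        cfg = PNPopulationConfig(odor_window=(0.0, 1.0))
        r = rates_fixed(cfg, 0)
        i = int(np.flatnonzero(r.response_class == CLASS_EXCITED)[0])
        t = np.linspace(0.0, 1.0, 20_000, endpoint=False)  # whole cycles
        assert r.rate(i, t).mean() == pytest.approx(20.0, rel=1e-3)

    def test_rates_nonnegative_everywhere(self):
        cfg = PNPopulationConfig(odor_window=(0.5, 1.5))
        r = rates_fixed(cfg, 3)
        t = np.linspace(0, 2.0, 5000)
        for i in range(0, cfg.n_pn, 97):
            assert np.all(r.rate(i, t) >= 0.0)


class TestShiftingScheme:
    def test_group_patterns(self):
        assert GROUP_PATTERNS == ("EEI", "EIE", "IEI", "IIE")

    def test_recruitment_fractions_over_first_four_cycles(self):
        cfg = PNPopulationConfig(n_pn=830, scheme="shifting",
                                 odor_window=(1.0, 2.0))
        r = rates_shifting(cfg, 3)
        members = np.flatnonzero((r.response_class == CLASS_SHIFTING)
                                 & (r.group_id == 0))
        fracs = []
        for cyc in range(4):
            t = np.array([1.0 + cyc * 0.05 + 0.02])
            active = sum(r.rate(int(i), t)[0] > 0 for i in members)
            fracs.append(active / len(members))
        np.testing.assert_allclose(fracs, [0.7, 0.8, 0.9, 1.0], atol=0.02)

    def test_simultaneous_excitation_bounded(self):
        cfg = PNPopulationConfig(n_pn=830, scheme="shifting",
                                 odor_window=(1.0, 2.0))
        r = rates_shifting(cfg, 5)
        for t0 in (1.02, 1.3, 1.55, 1.9):
            t = np.array([t0])
            active = sum(
                r.rate(i, t)[0] > cfg.spont_rate
                for i in range(cfg.n_pn))
            assert active / cfg.n_pn <= 0.35

    def test_inhibited_epoch_silences_group(self):
        cfg = PNPopulationConfig(n_pn=830, scheme="shifting",
                                 odor_window=(1.0, 2.0))
        r = rates_shifting(cfg, 3)
        # group 2 (IEI) silent in epoch 1, group 0 (EEI) silent in epoch 3
        g2 = int(np.flatnonzero((r.response_class == CLASS_SHIFTING)
                                & (r.group_id == 2))[0])
        assert r.rate(g2, np.array([1.2]))[0] == 0.0
        g0 = int(np.flatnonzero((r.response_class == CLASS_SHIFTING)
                                & (r.group_id == 0))[0])
        assert r.rate(g0, np.array([2.2]))[0] == 0.0

    def test_class_counts_invariant_to_seed(self):
        cfg = PNPopulationConfig(n_pn=830, scheme="shifting")
        a = rates_shifting(cfg, 1)
        b = rates_shifting(cfg, 2)
        for cls in (CLASS_SHIFTING, CLASS_SPONTANEOUS):
            assert (a.response_class == cls).sum() == \
                (b.response_class == cls).sum()


class TestPoissonSampling:
    def test_constant_rate_recovered(self):
        cfg = PNPopulationConfig(n_pn=260, odor_window=(200.0, 201.0),
                                 frac_excited=0.0, frac_inhibited=0.0)
        trains = sample_poisson(rates_fixed(cfg, 1), 2, 100.0)
        n_spont = (trains.response_class == CLASS_SPONTANEOUS).sum()
        assert n_spont == 200
        rate = trains.pooled_rate(classes=[CLASS_SPONTANEOUS])
        se = np.sqrt(2.6 / (n_spont * 100.0))
        assert abs(rate - 2.6) <= 3 * se

    def test_zero_rate_gives_empty_trains(self):
        cfg = PNPopulationConfig(n_pn=10, spont_rate=0.0, odor_rate=0.0)
        trains = sample_poisson(rates_fixed(cfg, 0), 0, 10.0)
        assert all(len(s) == 0 for s in trains.spikes)

    def test_seed_determinism_and_sorted_times(self):
        cfg = PNPopulationConfig(n_pn=40, odor_window=(0.5, 1.5))
        a = sample_poisson(rates_fixed(cfg, 1), 9, 2.0)
        b = sample_poisson(rates_fixed(cfg, 1), 9, 2.0)
        for sa, sb in zip(a.spikes, b.spikes):
            np.testing.assert_array_equal(sa, sb)
            assert np.all(np.diff(sa) >= 0)
            assert np.all((sa >= 0) & (sa <= 2.0))

    def test_fano_factor_near_one(self):
        cfg = PNPopulationConfig(n_pn=400, odor_window=(300.0, 301.0),
                                 frac_excited=0.0, frac_inhibited=0.0)
        trains = sample_poisson(rates_fixed(cfg, 2), 3, 50.0)
        idx = np.flatnonzero(trains.response_class == CLASS_SPONTANEOUS)
        counts = np.array([len(trains.spikes[i]) for i in idx])
        fano = counts.var(ddof=1) / counts.mean()
        # Fano estimator of a Poisson process: ~1 +/- sqrt(2/(n-1))
        se = np.sqrt(2.0 / (len(counts) - 1))
        assert abs(fano - 1.0) <= 3 * se

    def test_population_spectrum_peaks_at_lfp_frequency(self):
        cfg = PNPopulationConfig(n_pn=1000, odor_window=(0.0, 1.0))
        trains = sample_poisson(rates_fixed(cfg, 4), 5, 1.0)
        exc = np.flatnonzero(trains.response_class == CLASS_EXCITED)
        spikes = np.concatenate([trains.spikes[i] for i in exc]) * 1e3
        _, counts = population_psth(spikes, 5.0, (0.0, 1000.0))
        x = counts - counts.mean()
        freqs = np.fft.rfftfreq(len(x), d=0.005)
        power = np.abs(np.fft.rfft(x)) ** 2
        band = (freqs >= 5.0) & (freqs <= 45.0)
        assert freqs[band][np.argmax(power[band])] == pytest.approx(20.0,
                                                                    abs=1.0)
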