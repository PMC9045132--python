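"""Generator tests: determinism, spectral slope, waveform construction,
cohort structure and ground-truth bookkeeping."""

import numpy as np
import pytest

from sleepmci.preprocess import EPOCH_S, expand_hypnogram
from sleepmci.synth import (SimulationConfig, colored_noise, generate_cohort,
                            generate_recording, synth_slow_wave,
                            synth_spindle)


class TestColoredNoise:
    def test_deterministic_for_fixed_seed(self):
        a = colored_noise(1000, 1.0, 10.0, seed=7)
        b = colored_noise(1000, 1.0, 10.0, seed=7)
        assert np.array_equal(a, b)

    def test_length_mean_and_rms(self):
        x = colored_noise(10 ** 5, 1.0, 10.0, seed=1)
        assert x.size == 10 ** 5
        assert abs(x.mean()) < 0.5
        assert x.std() == pytest.approx(10.0, rel=1e-9)

    @pytest.mark.parametrize("beta", [0.0, 1.0, 2.0])
    def test_loglog_spectral_slope(self, beta):
        # average periodogram over 100 realizations, fit slope over the
        # mid-band (away from DC leakage and the Nyquist edge)
        n = 4096
        psds = []
        for seed in range(100):
            x = colored_noise(n, beta, 1.0, seed=seed)
            psds.append(np.abs(np.fft.rfft(x)) ** 2)
        mean_psd = np.mean(psds, axis=0)
        f = np.fft.rfftfreq(n)
        mask = (f > 0.01) & (f < 0.4)
        slope = np.polyfit(np.log(f[mask]), np.log(mean_psd[mask]), 1)[0]
        assert slope == pytest.approx(-beta, abs=0.1)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            colored_noise(1, 1.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            colored_noise(100, -0.5, 1.0, seed=0)


class TestSynthSpindle:
    def test_construction(self):
        burst = synth_spindle(13.0, 1.0, 25.0, 100.0)
        assert burst.size == 100
        assert abs(burst[0]) < 1e-6 and abs(burst[-1]) < 1e-6
        assert np.abs(burst).max() == pytest.approx(25.0, rel=0.01)

    def test_dominant_frequency(self):
        burst = synth_spindle(13.0, 2.0, 25.0, 100.0)
        f = np.fft.rfftfreq(burst.size, 1 / 100.0)
        peak = f[np.argmax(np.abs(np.fft.rfft(burst)))]
        assert peak == pytest.approx(13.0, abs=1.0)

    def test_frequency_bounds(self):
        with pytest.raises(ValueError):
            synth_spindle(10.0, 1.0, 25.0, 100.0)
        with pytest.raises(ValueError):
            synth_spindle(17.0, 1.0, 25.0, 100.0)


class TestSynthSlowWave:
    def test_ptp_and_length(self):
        wave = synth_slow_wave(150.0, 0.6, 0.4, 100.0)
        assert wave.size == 100
        assert np.ptp(wave) == pytest.approx(150.0, abs=3.0)

    def test_zero_crossing_between_phases(self):
        wave = synth_slow_wave(150.0, 0.6, 0.4, 100.0)
        # negative phase ends at 0.6 s
        assert np.all(wave[:60] <= 1e-9)
        assert wave[60:100].max() > 0

    def test_duration_bounds(self):
        with pytest.raises(ValueError):
            synth_slow_wave(150.0, 0.2, 0.4, 100.0)
        with pytest.raises(ValueError):
            synth_slow_wave(150.0, 0.6, 1.2, 100.0)


class TestGenerateCohort:
    def test_counts_and_labels(self):
        config = SimulationConfig(seed=3, stage_schedule=[("N2", 600.0)],
                                  artifact_rate=0.0)
        recs, hyps, truths, labels = generate_cohort(config, 2, 2)
        assert len(recs) == 4
        assert labels == [0, 0, 1, 1]
        assert hyps[0].n_epochs == 600 / EPOCH_S

    def test_fixed_seed_bit_identical(self):
        config = SimulationConfig(seed=11, stage_schedule=[("N2", 300.0)])
        a = generate_cohort(config, 1, 1)
        b = generate_cohort(config, 1, 1)
        for ra, rb in zip(a[0], b[0]):
            assert np.array_equal(ra.data, rb.data)
        assert a[2][0].spindles == b[2][0].spindles

    def test_mci_spindle_reduction_on_ground_truth(self):
        hc_counts, mci_counts = [], []
        for seed in range(20):
            config = SimulationConfig(seed=seed,
                                      stage_schedule=[("N2", 600.0)],
                                      mci_spindle_factor=0.5)
            _, _, truths, labels = generate_cohort(config, 1, 1)
            for truth, label in zip(truths, labels):
                n = sum(len(v) for v in truth.spindles.values())
                (mci_counts if label else hc_counts).append(n)
        assert np.mean(mci_counts) < np.mean(hc_counts)

    def test_events_inside_eligible_stages(self):
        config = SimulationConfig(seed=5)
        rec, hyp, truth = generate_recording(config, False, "s1", 5)
        stage_vec = expand_hypnogram(hyp, config.sampling_rate)
        fs = config.sampling_rate
        for ch, events in truth.spindles.items():
            for start, end, _f, _a in events:
                stages = stage_vec[int(start * fs):int(end * fs)]
                assert np.all(stages == 2)  # N2 only
        for ch, events in truth.slow_waves.items():
            for start, end, _ptp in events:
                stages = stage_vec[int(start * fs):int(end * fs)]
                assert np.all(np.isin(stages, [2, 3]))

    def test_same_type_events_non_overlapping(self):
        config = SimulationConfig(seed=9, spindle_rate=6.0, sw_rate=10.0)
        _, _, truth = generate_recording(config, False, "s1", 9)
        for events in list(truth.spindles.values()) + list(truth.slow_waves.values()):
            intervals = sorted((e[0], e[1]) for e in events)
            for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
                assert s1 >= e0

    def test_zero_rates_give_no_events(self):
        config = SimulationConfig(seed=1, spindle_rate=0.0, sw_rate=0.0,
                                  artifact_rate=0.0)
        _, _, truth = generate_recording(config, False, "s1", 1)
        assert all(not v for v in truth.spindles.values())
        assert all(not v for v in truth.slow_waves.values())
        assert all(not v for v in truth.artifacts.values())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(sampling_rate=50)
        with pytest.raises(ValueError):
            SimulationConfig(spindle_freq_range=(10.0, 14.0))
        with pytest.raises(ValueError):
            SimulationConfig(stage_schedule=[("N2", 45.0)])
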