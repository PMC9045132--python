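"""Filtering, resampling, hypnogram expansion and segment QC tests."""

import numpy as np
import pytest

from sleepmci.preprocess import (Hypnogram, Recording, bandpass_fir,
                                 expand_hypnogram, resample_to,
                                 segment_and_reject)
from sleepmci.synth import colored_noise

FS = 100.0


def _sine(freq, n=20000, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestBandpassFir:
    def test_dc_rejected(self):
        out = bandpass_fir(np.full(20000, 5.0), FS, 0.1, 30.0)
        assert np.sqrt((out ** 2).mean()) < 0.05  # < 1% of amplitude

    def test_passband_gain(self):
        x = _sine(10.0)
        out = bandpass_fir(x, FS, 0.1, 30.0)
        core = slice(5000, 15000)  # avoid edge transients
        assert out[core].std() == pytest.approx(x[core].std(), rel=0.05)

    def test_stopband_attenuation(self):
        x = _sine(45.0)
        out = bandpass_fir(x, FS, 0.1, 30.0)
        core = slice(5000, 15000)
        atten_db = 20 * np.log10(x[core].std() / out[core].std())
        assert atten_db > 20

    def test_high_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_fir(np.zeros(1000), FS, 0.1, 60.0)


class TestResampleTo:
    def test_length(self):
        out = resample_to(np.zeros(2000), 200.0, 100.0)
        assert out.size == 1000

    def test_tone_preserved(self):
        x = np.sin(2 * np.pi * 10.0 * np.arange(4000) / 200.0)
        out = resample_to(x, 200.0, 100.0)
        f = np.fft.rfftfreq(out.size, 1 / 100.0)
        peak = f[np.argmax(np.abs(np.fft.rfft(out)))]
        assert peak == pytest.approx(10.0, abs=0.2)

    def test_identity_and_upsample_refusal(self):
        x = np.arange(100.0)
        assert np.array_equal(resample_to(x, 100.0, 100.0), x)
        with pytest.raises(ValueError):
            resample_to(x, 100.0, 200.0)


class TestExpandHypnogram:
    def test_expansion(self):
        hyp = Hypnogram(np.array([2, 0]))
        vec = expand_hypnogram(hyp, FS)
        assert vec.size == 6000
        assert np.all(vec[:3000] == 2) and np.all(vec[3000:] == 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            Hypnogram(np.array([]))

    def test_length_mismatch_reported(self):
        rec = Recording(np.zeros((1, 5000)), FS, ["C3"])
        hyp = Hypnogram(np.array([2, 2]))  # expands to 6000 != 5000
        with pytest.raises(ValueError, match="mismatch"):
            segment_and_reject(rec, hyp)


def _recording_with_stages(stages, seed=0, n_channels=2):
    n = len(stages) * int(30 * FS)
    rng = np.random.default_rng(seed)
    data = np.vstack([colored_noise(n, 1.0, 10.0, rng)
                      for _ in range(n_channels)])
    labels = ["C3", "C4"][:n_channels]
    return Recording(data, FS, labels), Hypnogram(np.array(stages))


class TestSegmentAndReject:
    def test_20_minutes_n2_gives_4_segments_per_channel(self):
        rec, hyp = _recording_with_stages([2] * 40)  # 1200 s of N2
        segments, report = segment_and_reject(rec, hyp)
        nrem = [s for s in segments if s.state == "NREM"]
        assert len(nrem) == 4 * 2  # 4 windows x 2 channels
        assert report.n_kept == 4

    def test_high_variance_segment_rejected(self):
        rec, hyp = _recording_with_stages([2] * 200, seed=3)  # 20 windows
        rec.data[:, 3000:6000] *= 10.0  # blow up part of window 0
        segments, report = segment_and_reject(rec, hyp, z_thresh=3.0)
        starts = {s.start_s for s in segments if s.state == "NREM"}
        assert 0.0 not in starts
        assert report.dropped_std >= 1
        # brute-force check: z of log-std of the corrupted window exceeds 3
        seg_n = int(300 * FS)
        stds = np.array([[rec.data[c, i * seg_n:(i + 1) * seg_n].std()
                          for c in range(2)] for i in range(20)])
        logs = np.log(stds)
        z = (logs - logs.mean()) / logs.std()
        assert np.abs(z[0]).max() > 3.0

    def test_stage_transition_blocks_nrem_segment(self):
        # 5 min N2 then wake: segment straddling the transition not emitted
        rec, hyp = _recording_with_stages([2] * 9 + [0] * 11)
        segments, _ = segment_and_reject(rec, hyp)
        assert all(s.state != "NREM" for s in segments)

    def test_annotation_overlap_dropped_first(self):
        rec, hyp = _recording_with_stages([2] * 40)
        segments, report = segment_and_reject(rec, hyp,
                                              annotations=[(310.0, 312.0)])
        starts = {s.start_s for s in segments}
        assert 300.0 not in starts
        assert report.dropped_annotation == 1

    def test_kept_plus_dropped_equals_candidates(self):
        rec, hyp = _recording_with_stages([2] * 100 + [0] * 30, seed=4)
        rec.data[:, 0:2000] *= 8.0
        _, report = segment_and_reject(rec, hyp, annotations=[(3001.0, 3004.0)])
        assert (report.n_kept + report.dropped_annotation
                + report.dropped_std) == report.n_candidates

    def test_rejection_invariant_to_global_rescaling(self):
        rec, hyp = _recording_with_stages([2] * 100, seed=5)
        rec.data[:, 5000:8000] *= 6.0
        _, rep1 = segment_and_reject(rec, hyp)
        rec2 = Recording(rec.data * 37.5, FS, ["C3", "C4"])
        _, rep2 = segment_and_reject(rec2, hyp)
        assert rep1.as_dict() == rep2.as_dict()

    def test_no_eligible_span_returns_empty(self):
        rec, hyp = _recording_with_stages([1] * 20)  # N1 only
        segments, report = segment_and_reject(rec, hyp)
        assert segments == []
        assert report.n_candidates == 0

    def test_segments_tile_left_to_right_without_overlap(self):
        rec, hyp = _recording_with_stages([2] * 35)  # 1050 s -> 3 windows
        segments, _ = segment_and_reject(rec, hyp)
        starts = sorted({s.start_s for s in segments if s.state == "NREM"})
        assert starts == [0.0, 300.0, 600.0]
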