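import numpy as np
import pytest
from scipy import signal as sps

import emgwean as ew
from emgwean.derive import (BeatSeries, compute_edr, compute_emge,
                            compute_emgi, compute_hrv, correct_hrv_outliers,
                            detect_r_peaks, max_xcorr)
from emgwean.spectral import band_parameters


def _qrs_train(beat_times, amps, fs=128.0, dur=None):
    dur = dur if dur is not None else beat_times[-1] + 1.0
    n = int(dur * fs)
    x = np.zeros(n)
    half = int(round(0.08 * fs))
    t = np.arange(-half, half + 1) / fs
    u = (t / 0.02) ** 2
    w = (1 - u) * np.exp(-u / 2)
    for bt, a in zip(beat_times, amps):
        i = int(round(bt * fs))
        lo, hi = i - half, i + half + 1
        if lo >= 0 and hi <= n:
            x[lo:hi] += a * w
    return x


class TestRPeakDetection:
    def test_count_and_rate_on_regular_train(self):
        beats = np.arange(0.5, 120.0, 1.0)
        x = _qrs_train(beats, np.ones_like(beats))
        got = detect_r_peaks(x, 128.0)
        assert abs(len(got.r_peak_times) - 120) <= 1
        assert got.rr_intervals.mean() == pytest.approx(1.0, abs=0.01)

    def test_flat_line_raises(self):
        with pytest.raises(ValueError, match="insufficient beats"):
            detect_r_peaks(np.zeros(128 * 20), 128.0)

    def test_modulation_depth_recovered_in_amplitudes(self):
        beats = np.arange(0.5, 240.0, 0.8)
        amps = 1.0 + 0.3 * np.sin(2 * np.pi * 0.3 * beats)
        x = _qrs_train(beats, amps)
        got = detect_r_peaks(x, 128.0)
        a = got.r_peak_to_peak
        swing = (a.max() - a.min()) / a.mean()
        assert swing == pytest.approx(0.6, rel=0.10)

    def test_beat_series_invariants(self):
        with pytest.raises(ValueError, match="increasing"):
            BeatSeries(np.array([1.0, 0.5, 2.0]), np.ones(3))
        with pytest.raises(ValueError, match="non-negative"):
            BeatSeries(np.array([0.5, 1.0]), np.array([1.0, -0.1]))


class TestEdr:
    def test_constant_amplitudes_give_constant_edr(self):
        b = BeatSeries(np.arange(0.0, 50.0, 1.0), np.full(50, 2.5))
        _, edr = compute_edr(b, 4.0)
        np.testing.assert_allclose(edr, 2.5, atol=1e-12)

    def test_no_overshoot_beyond_amplitude_range(self):
        rng = np.random.default_rng(0)
        amps = rng.uniform(0.5, 2.0, 100)
        b = BeatSeries(np.arange(100) * 0.8, amps)
        _, edr = compute_edr(b, 4.0)
        assert edr.min() >= amps.min() - 1e-12
        assert edr.max() <= amps.max() + 1e-12

    def test_modulation_peak_recovered(self):
        t = np.arange(0.0, 900.0, 0.8)
        b = BeatSeries(t, 1.0 + 0.3 * np.sin(2 * np.pi * 0.30 * t))
        _, edr = compute_edr(b, 4.0)
        est = ew.welch_psd(edr, 4.0, seg_len_s=300.0)
        bp = band_parameters(est.frequencies, est.power, (0.15, 0.4))
        assert bp.fp == pytest.approx(0.30, abs=0.02)


class TestHrv:
    def test_constant_rr_constant_rate(self):
        b = BeatSeries(np.arange(0.0, 60.0, 1.0), np.ones(60))
        _, hrv = compute_hrv(b, 4.0)
        np.testing.assert_allclose(hrv, 1.0, atol=1e-9)
        assert np.var(hrv) < 1e-18

    def test_single_outlier_corrected_within_rule(self):
        rr = np.full(100, 1.0)
        rr[50] = 1.4                      # 40 % rate deviation
        times = np.concatenate([[0.0], np.cumsum(rr)])
        b = BeatSeries(times, np.ones(times.size))
        _, hrv = compute_hrv(b, 4.0)
        rate = 1.0 / b.rr_intervals
        corrected = correct_hrv_outliers(rate, times[1:])
        dev = np.abs(corrected - corrected.mean()) / corrected.mean()
        assert dev.max() <= 0.18

    def test_outlier_rule_on_adversarial_series(self):
        """Clustered spikes, edge spikes and drop-outs all end within the
        18 %-of-mean band after recursive correction."""
        rng = np.random.default_rng(1)
        rate = 1.2 + 0.05 * rng.standard_normal(300)
        rate[:3] = 3.0                    # run of edge outliers
        rate[150:155] = 0.4               # clustered drop-out
        rate[-1] = 5.0                    # extrapolation trap at the end
        rate[200] = 2.4
        times = np.cumsum(np.full(300, 0.8))
        out = correct_hrv_outliers(rate, times)
        dev = np.abs(out - out.mean()) / abs(out.mean())
        assert dev.max() <= 0.18

    def test_modulated_rr_spectral_peak(self):
        times = [0.3]
        while times[-1] < 900.0:
            rr = 0.8 * (1 + 0.05 * np.sin(2 * np.pi * 0.25 * times[-1]))
            times.append(times[-1] + rr)
        b = BeatSeries(np.array(times), np.ones(len(times)))
        _, hrv = compute_hrv(b, 4.0)
        est = ew.welch_psd(hrv, 4.0, seg_len_s=300.0)
        bp = band_parameters(est.frequencies, est.power, (0.15, 0.4))
        assert bp.fp == pytest.approx(0.25, abs=0.02)


class TestEmgEnvelopes:
    @staticmethod
    def _bursts(fs=128.0, dur=900.0, rate=0.3, rng=None):
        rng = rng or np.random.default_rng(2)
        t = np.arange(0, dur, 1 / fs)
        env = np.clip(np.sin(2 * np.pi * rate * t), 0.0, None) ** 2
        return (0.05 + env) * rng.standard_normal(t.size)

    def test_burst_rate_appears_in_envelope_spectrum(self):
        x = self._bursts()
        _, emge = compute_emge(x, 128.0, 4.0)
        est = ew.welch_psd(emge, 4.0, seg_len_s=300.0)
        bp = band_parameters(est.frequencies, est.power, (0.15, 0.4))
        assert bp.fp == pytest.approx(0.30, abs=0.02)

    def test_constant_noise_gives_flat_envelope(self):
        x = np.random.default_rng(3).standard_normal(128 * 120)
        _, emge = compute_emge(x, 128.0, 4.0)
        assert np.std(emge) / np.mean(emge) < 0.2

    def test_scaling_linearity(self):
        x = self._bursts(dur=120.0)
        g1, e1 = compute_emge(x, 128.0, 4.0)
        g2, e2 = compute_emge(2 * x, 128.0, 4.0)
        np.testing.assert_allclose(e2, 2 * e1, rtol=1e-9)

    def test_emgi_minimum_separation_keeps_larger(self):
        fs = 128.0
        x = np.zeros(int(fs * 60))
        spikes = {}
        # two conflicting peaks 0.10 s apart: second, larger one survives
        for t0, a in [(10.0, 1.0), (10.10, 2.0)]:
            spikes[int(t0 * fs)] = a
        # pair 0.2 s apart: both survive
        for t0, a in [(30.0, 1.5), (30.2, 1.4)]:
            spikes[int(t0 * fs)] = a
        for i, a in spikes.items():
            x[i] = a
        rect = np.abs(x)
        thr = np.quantile(rect, 0.70)
        locs, _ = sps.find_peaks(rect, height=max(thr, 0.5),
                                 distance=int(round(0.15 * fs)))
        kept = set(locs)
        assert int(10.10 * fs) in kept and int(10.0 * fs) not in kept
        assert {int(30.0 * fs), int(30.2 * fs)} <= kept

    def test_emgi_tracks_envelope(self):
        x = self._bursts(dur=300.0)
        grid = np.arange(5.0, 295.0, 0.25)
        _, emge = compute_emge(x, 128.0, 4.0, grid=grid)
        _, emgi = compute_emgi(x, 128.0, 4.0, grid=grid)
        assert np.corrcoef(emge, emgi)[0, 1] > 0.7


class TestChannelSelection:
    def test_identical_series_correlate_fully(self):
        x = np.sin(np.linspace(0, 60, 480))
        assert max_xcorr(x, x, 4.0) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_decorrelated(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals.append(abs(max_xcorr(rng.standard_normal(2400),
                                      rng.standard_normal(2400), 4.0)))
        assert np.mean(vals) < 0.2

    def test_zero_variance_series_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            max_xcorr(np.zeros(100), np.ones(100), 4.0)

    def test_synthetic_default_selects_channel3_lead2(self, demo_derived):
        assert (demo_derived.emg_channel, demo_derived.ecg_lead) == (2, 1)
        assert demo_derived.xcorr > 0.4


class TestDerivedSet:
    def test_series_finite_aligned_and_uniform(self, demo_derived):
        d = demo_derived
        for s in d.signals().values():
            assert s.shape == d.t.shape
            assert np.all(np.isfinite(s))
        np.testing.assert_allclose(np.diff(d.t), 1.0 / d.fa, atol=1e-9)
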