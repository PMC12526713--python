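import numpy as np
import pytest

import emgwean as ew
from emgwean.derive import DerivedSignalSet
from emgwean.spectral import (band_parameters, coherence_parameters,
                              iter_windows, msc, n_segments, welch_psd,
                              windowed_params)


def _fake_dset(signals, fa=4.0):
    n = len(next(iter(signals.values())))
    t = np.arange(n) / fa
    return DerivedSignalSet(t=t, edr=signals["EDR"], hrv=signals["HRV"],
                            emge=signals["EMGe"], emgi=signals["EMGi"],
                            fa=fa, emg_channel=2, ecg_lead=1, xcorr=0.5)


class TestWelch:
    def test_segment_count_arithmetic(self):
        # 3600 s at 300-s segments, 50 % overlap -> 1 + (3600-300)/150
        assert n_segments(3600 * 4, 300 * 4, 150 * 4) == 23
        est = welch_psd(np.random.default_rng(0).standard_normal(14400),
                        4.0, 300.0, 0.5)
        assert est.n_segments == 23

    def test_parseval_white_noise(self):
        x = np.random.default_rng(1).normal(0, np.sqrt(2.0), 14400)
        est = welch_psd(x, 4.0, 300.0, 0.5)
        total = np.trapezoid(est.power, est.frequencies)
        assert total == pytest.approx(2.0, rel=0.05)

    def test_sine_peak_bin(self):
        t = np.arange(0, 1200, 0.25)
        est = welch_psd(np.sin(2 * np.pi * 0.30 * t), 4.0, 300.0, 0.5)
        f_peak = est.frequencies[np.argmax(est.power)]
        df = est.frequencies[1] - est.frequencies[0]
        assert abs(f_peak - 0.30) <= df

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter than one segment"):
            welch_psd(np.zeros(100), 4.0, 300.0)


class TestBandParameters:
    def test_triangular_spectrum_closed_form(self):
        f = np.linspace(0.15, 0.40, 26)
        fp_true, a = 0.25, 3.0
        power = np.where(f <= fp_true,
                         a * (f - 0.15) / (fp_true - 0.15),
                         a * (0.40 - f) / (0.40 - fp_true))
        bp = band_parameters(f, power, (0.15, 0.40))
        assert bp.hp == pytest.approx(a)
        assert bp.fp == pytest.approx(fp_true)
        assert bp.us == pytest.approx(a / (fp_true - 0.15))
        assert bp.ds == pytest.approx(-a / (0.40 - fp_true))

    def test_flat_spectrum_tie_breaks_low_and_flags_edge(self):
        f = np.linspace(0.15, 0.40, 26)
        bp = band_parameters(f, np.ones_like(f), (0.15, 0.40))
        assert bp.fp == pytest.approx(0.15)
        assert bp.us == 0.0
        assert bp.edge_peak

    def test_tone_power_concentrates_in_its_band(self):
        t = np.arange(0, 3600, 0.25)
        est = welch_psd(np.sin(2 * np.pi * 0.30 * t), 4.0, 300.0, 0.5)
        lf = band_parameters(est.frequencies, est.power, (0.04, 0.15))
        hf = band_parameters(est.frequencies, est.power, (0.15, 0.40))
        assert hf.fp == pytest.approx(0.30, abs=0.004)
        assert lf.p < 0.01 * hf.p

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(4800)
        e1 = welch_psd(x, 4.0, 300.0)
        e2 = welch_psd(3.0 * x, 4.0, 300.0)
        b1 = band_parameters(e1.frequencies, e1.power, (0.15, 0.40))
        b2 = band_parameters(e2.frequencies, e2.power, (0.15, 0.40))
        assert b2.hp == pytest.approx(9.0 * b1.hp, rel=1e-9)
        assert b2.p == pytest.approx(9.0 * b1.p, rel=1e-9)
        assert b2.fp == b1.fp

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            band_parameters(np.linspace(0, 2, 100), np.ones(100),
                            (1.9999, 2.0))


class TestCoherence:
    def test_identical_signals_full_coherence(self):
        x = np.random.default_rng(3).standard_normal(4800)
        _, k = msc(x, x, 4.0, 60.0, 0.5)
        np.testing.assert_allclose(k, 1.0, atol=1e-9)

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(4800), rng.standard_normal(4800)
        f, kxy = msc(x, y, 4.0, 60.0, 0.5)
        _, kyx = msc(y, x, 4.0, 60.0, 0.5)
        assert np.all((kxy >= 0.0) & (kxy <= 1.0))
        np.testing.assert_allclose(kxy, kyx, atol=1e-12)

    def test_independent_noise_low_mean_coherence(self):
        # MSC bias ~ 1/L with L=16 averaged segments
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 16 * 240 // 2 + 120       # 16 segments of 60 s at 50 %
            x, y = rng.standard_normal(2040), rng.standard_normal(2040)
            f, k = msc(x, y, 4.0, 60.0, 0.5)
            m = (f >= 0.04) & (f <= 0.4)
            means.append(k[m].mean())
        assert np.mean(means) < 0.25

    def test_delayed_copy_high_coherence(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4801)
        y = x[1:] + 0.05 * rng.standard_normal(4800)
        f, k = msc(x[:-1], y, 4.0, 60.0, 0.5)
        m = (f >= 0.04) & (f <= 0.4)
        assert k[m].mean() > 0.9

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError, match="insufficient segments"):
            msc(np.zeros(500), np.zeros(500), 4.0, 60.0, 0.5)


class TestCoherenceParameters:
    def test_unit_coherence(self):
        f = np.linspace(0.0, 2.0, 201)
        out = coherence_parameters(f, np.ones_like(f), (0.15, 0.40))
        assert out["RMScoh"] == pytest.approx(1.0)
        assert out["Pcoh"] == pytest.approx(0.25)
        assert out["Hpcoh_0.02Hz"] == 1.0
        assert out["Hpcoh_0.04Hz"] == 1.0

    def test_constant_half_coherence(self):
        f = np.linspace(0.0, 2.0, 201)
        out = coherence_parameters(f, np.full_like(f, 0.5), (0.15, 0.40))
        assert out["RMScoh"] == pytest.approx(0.5)

    def test_constructed_unimodal_closed_form(self):
        f = np.linspace(0.0, 0.5, 51)
        k = np.exp(-((f - 0.25) / 0.05) ** 2)
        out = coherence_parameters(f, k, (0.15, 0.40))
        assert out["Fpcoh"] == pytest.approx(0.25)
        assert out["Hpcoh"] == pytest.approx(1.0)
        band = (f >= 0.15) & (f <= 0.40)
        assert out["Pcoh"] == pytest.approx(np.trapezoid(k[band], f[band]))
        assert out["RMScoh"] == pytest.approx(
            np.sqrt(np.mean(k[band] ** 2)))

    def test_fixed_frequency_outside_grid_rejected(self):
        f = np.linspace(0.1, 0.5, 41)
        with pytest.raises(ValueError, match="outside the grid"):
            coherence_parameters(f, np.ones_like(f), (0.15, 0.4),
                                 fixed_freqs=(0.02,))


class TestTimeVaryingLayer:
    def test_window_arithmetic_3600s(self):
        ws = list(iter_windows(14400, 4.0, 300.0, 0.5))
        assert len(ws) == 23

    def test_every_param_series_has_one_value_per_window(self):
        rng = np.random.default_rng(6)
        t = np.arange(0, 3600, 0.25)
        mk = lambda: (np.sin(2 * np.pi * 0.3 * t)
                      + 0.5 * rng.standard_normal(t.size))
        dset = _fake_dset({"EDR": mk(), "HRV": mk(), "EMGe": mk(),
                           "EMGi": mk()})
        params = windowed_params(dset)
        assert len(params) == 72          # 40 spectral + 32 coherence
        for ps in params.values():
            assert ps.values.size == 23

    def test_stationary_band_power_stable(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 3600, 0.25)
        mk = lambda: (np.sin(2 * np.pi * 0.3 * t)
                      + 0.3 * rng.standard_normal(t.size))
        dset = _fake_dset({"EDR": mk(), "HRV": mk(), "EMGe": mk(),
                           "EMGi": mk()})
        params = windowed_params(dset)
        for name in ("PHFEDR", "PHFEMGe"):
            v = params[name].values
            assert np.std(v, ddof=1) / np.mean(v) < 0.5

    def test_amplitude_step_widens_envelope_param_spread(self):
        rng = np.random.default_rng(8)
        t = np.arange(0, 3600, 0.25)
        base = np.sin(2 * np.pi * 0.3 * t) + 0.2 * rng.standard_normal(t.size)
        stepped = base.copy()
        stepped[t.size // 2:] *= 3.0
        mk = lambda: base + 0.01 * rng.standard_normal(t.size)
        d_stat = _fake_dset({"EDR": mk(), "HRV": mk(), "EMGe": base,
                             "EMGi": mk()})
        d_step = _fake_dset({"EDR": mk(), "HRV": mk(), "EMGe": stepped,
                             "EMGi": mk()})
        iqr = lambda v: np.subtract(*np.percentile(v, [75, 25]))
        hp_stat = windowed_params(d_stat)["HpHFEMGe"].values
        hp_step = windowed_params(d_step)["HpHFEMGe"].values
        assert iqr(hp_step) > iqr(hp_stat)

    def test_too_short_recording_rejected(self):
        t = np.arange(0, 400, 0.25)
        x = np.sin(t)
        dset = _fake_dset({"EDR": x, "HRV": x, "EMGe": x, "EMGi": x})
        with pytest.raises(ValueError, match="two outer"):
            windowed_params(dset)
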