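"""Filtering, resampling, despiking and SNR quantification.

All filters are zero-phase (forward-backward) second-order-section IIR:
a quality-factor-35 notch at the mains frequency on both modalities, a
0.05 Hz high-pass on the ECG and a 20 Hz high-pass on the sEMG, followed by
linear detrending.  The sEMG is then polyphase-resampled from 1 kHz to
128 Hz so both modalities share one clock.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import signal as sps

from .io import PipelineConfig, Recording

logger = logging.getLogger("emgwean")


@dataclasses.dataclass
class CleanRecording:
    """Preprocessed recording: 8 channels on a common 128 Hz clock.

    ``snr_db`` holds the smooth-baseline SNR estimate per channel (3 ECG
    then 5 sEMG); for raw broadband channels this estimator is conservative
    (see :func:`compute_snr`).  ``provenance`` lists the filters applied in
    order.
    """

    patient_id: str
    group: str
    ecg: np.ndarray          # (3, n) @ fs
    semg: np.ndarray         # (5, n) @ fs (resampled)
    fs: float
    snr_db: np.ndarray
    provenance: tuple

    @property
    def duration(self) -> float:
        return self.ecg.shape[1] / self.fs


def _notch_ba(freq, q, fs):
    return sps.iirnotch(freq, q, fs=fs)


def _detrend_linear(y: np.ndarray) -> np.ndarray:
    """Closed-form least-squares linear detrend along the last axis."""
    y = np.atleast_2d(y)
    n = y.shape[-1]
    t = np.arange(n) - (n - 1) / 2.0
    ym = y - y.mean(axis=-1, keepdims=True)
    slope = ym @ t / np.dot(t, t)
    return np.squeeze(ym - slope[..., None] * t)


def apply_filters(rec: Recording, cfg: PipelineConfig | None = None) -> Recording:
    """Zero-phase notch + high-pass filtering and linear detrending.

    ECG: notch at ``cfg.notch_hz`` then ``cfg.hp_ecg_hz`` high-pass.
    sEMG: notch then ``cfg.hp_emg_hz`` high-pass.  Raises if any cutoff is
    at or above the channel's Nyquist frequency.
    """
    cfg = cfg or PipelineConfig()
    for cut, fs in ((cfg.notch_hz, rec.fs_ecg), (cfg.hp_ecg_hz, rec.fs_ecg),
                    (cfg.notch_hz, rec.fs_emg), (cfg.hp_emg_hz, rec.fs_emg)):
        if cut >= fs / 2.0:
            raise ValueError(f"cutoff {cut} Hz at or above Nyquist of {fs} Hz")

    def chain(x, fs, hp_cut):
        b, a = _notch_ba(cfg.notch_hz, cfg.notch_q, fs)
        sos = np.vstack([
            sps.tf2sos(b, a),
            sps.butter(cfg.filter_order, hp_cut, btype="highpass", fs=fs,
                       output="sos"),
        ])
        y = sps.sosfiltfilt(sos, x, axis=-1)
        return _detrend_linear(y)

    ecg = chain(rec.ecg, rec.fs_ecg, cfg.hp_ecg_hz)
    semg = chain(rec.semg, rec.fs_emg, cfg.hp_emg_hz)
    logger.info("filtered %s: notch %g Hz (Q=%g), HP %g/%g Hz, detrend",
                rec.patient_id, cfg.notch_hz, cfg.notch_q, cfg.hp_ecg_hz,
                cfg.hp_emg_hz)
    return Recording(patient_id=rec.patient_id, group=rec.group, ecg=ecg,
                     semg=semg, fs_ecg=rec.fs_ecg, fs_emg=rec.fs_emg,
                     meta=dict(rec.meta))


def resample_semg(x: np.ndarray, fs_in: float = 1000.0,
                  fs_out: float = 128.0) -> np.ndarray:
    """Polyphase rational resampling with anti-alias filtering.

    For the canonical 1000 -> 128 Hz conversion the ratio is 16/125.
    """
    frac = math.gcd(int(round(fs_out)), int(round(fs_in)))
    up, down = int(round(fs_out)) // frac, int(round(fs_in)) // frac
    # long Kaiser-windowed FIR for a steep anti-alias transition near the
    # output Nyquist (the default filter leaks tones just above it)
    ntaps = 40 * max(up, down) + 1
    h = sps.firwin(ntaps, 0.94 / max(up, down), window=("kaiser", 8.0))
    return sps.resample_poly(np.asarray(x, dtype=float), up, down, axis=-1,
                             window=h)


def despike(x: np.ndarray, z_thresh: float = 8.0) -> np.ndarray:
    """Replace samples with robust z-score > ``z_thresh`` by interpolation.

    The robust z-score uses the median and the MAD (scaled to sigma);
    flagged samples are filled by linear interpolation from their
    neighbours.  All-constant input is returned unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("despike needs at least 3 samples")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x.copy()
    z = np.abs(x - med) / (1.4826 * mad)
    bad = z > z_thresh
    out = x.copy()
    if bad.any():
        good = ~bad
        out[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good),
                             x[good])
        logger.info("despike: replaced %d/%d samples (z>%g)", int(bad.sum()),
                    x.size, z_thresh)
    return out


def compute_snr(x: np.ndarray, fs: float, window_s: float = 0.5,
                polyorder: int = 3) -> float:
    """Smooth-baseline SNR estimate in dB.

    The signal estimate is a least-squares local-polynomial
    (Savitzky-Golay) baseline of order ``polyorder`` over a ``window_s``
    window; the noise is the residual.  Returns
    ``10*log10(P_baseline / P_residual)``, ``+inf`` if the residual power
    is exactly zero.

    The estimate is meaningful when the clean component of ``x`` lies
    within the baseline passband (roughly below ``2/window_s`` Hz) — e.g.
    respiration-scale derived series or envelopes.  On raw broadband
    signals the fast signal content is counted as noise, so the value is a
    conservative quality floor, not a physical SNR.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(window_s * fs))
    win = max(win | 1, polyorder + 2 + ((polyorder + 2) % 2 == 0))  # odd, > order
    if x.size < 2 * win:
        raise ValueError("series shorter than two SNR analysis windows")
    baseline = sps.savgol_filter(x, win, polyorder)
    resid = x - baseline
    p_sig = float(np.var(baseline))
    p_noise = float(np.mean(resid ** 2))
    if p_noise <= 1e-14 * max(p_sig, np.finfo(float).tiny):
        logger.info("compute_snr: zero residual power, returning +inf")
        return float("inf")
    return 10.0 * np.log10(p_sig / p_noise)


def preprocess_recording(rec: Recording,
                         cfg: PipelineConfig | None = None) -> CleanRecording:
    """Full preprocessing: filters, despiking, resampling, SNR, alignment."""
    cfg = cfg or PipelineConfig()
    filt = apply_filters(rec, cfg)

    def z_adapt(ch):
        # Impulsive physiological content (QRS complexes, EMG bursts) has
        # huge MAD-scale z-scores of its own; only flag samples far beyond
        # the channel's bulk extreme-value scale so despiking removes
        # isolated artifacts, not the signal.
        med = np.median(ch)
        mad = np.median(np.abs(ch - med))
        if mad == 0:
            return cfg.despike_z
        z999 = np.percentile(np.abs(ch - med), 99.9) / (1.4826 * mad)
        return max(cfg.despike_z, 3.0 * z999)

    ecg = np.vstack([despike(ch, z_adapt(ch)) for ch in filt.ecg])
    semg_hi = np.vstack([despike(ch, z_adapt(ch)) for ch in filt.semg])
    semg = resample_semg(semg_hi, rec.fs_emg, rec.fs_ecg)
    n = min(ecg.shape[1], semg.shape[1])
    ecg, semg = ecg[:, :n], semg[:, :n]
    snr = np.array(
        [compute_snr(ch, rec.fs_ecg, cfg.snr_window_s, cfg.snr_polyorder)
         for ch in ecg]
        + [compute_snr(ch, rec.fs_ecg, cfg.snr_window_s, cfg.snr_polyorder)
           for ch in semg]
    )
    prov = (f"notch{cfg.notch_hz:g}Q{cfg.notch_q:g}",
            f"hp_ecg{cfg.hp_ecg_hz:g}", f"hp_emg{cfg.hp_emg_hz:g}",
            "detrend", f"despike_z{cfg.despike_z:g}",
            f"resample{rec.fs_emg:g}->{rec.fs_ecg:g}")
    return CleanRecording(patient_id=rec.patient_id, group=rec.group,
                          ecg=ecg, semg=semg, fs=rec.fs_ecg, snr_db=snr,
                          provenance=prov)
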