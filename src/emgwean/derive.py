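"""Derived analysis signals: EDR, HRV, EMGe, EMGi and channel selection.

From the preprocessed 128 Hz channels this module builds the four uniformly
sampled series the time-varying analysis consumes, all on one common grid
at the analysis rate ``fa`` (default 4 Hz):

* **EDR** — ECG-derived respiration: beat-to-beat QRS peak-to-peak
  amplitudes, shape-preserving (PCHIP) interpolated;
* **HRV** — instantaneous heart rate 1/RR, recursively outlier-corrected
  (18 % of the mean rule), cubic-spline interpolated at 1 Hz and upsampled
  to ``fa``;
* **EMGe** — diaphragm EMG envelope: spline through rectified-signal peaks
  with short quadratic-polynomial smoothing;
* **EMGi** — interpolated supra-threshold EMG peak series with a 0.15 s
  minimum peak separation.

The representative (EMG channel, ECG lead) pair is chosen by maximising the
normalised cross-correlation between the per-channel EMGe and per-lead EDR
series over lags up to +-5 s.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline, PchipInterpolator

from .io import PipelineConfig
from .preprocess import CleanRecording

logger = logging.getLogger("emgwean")

RR_MIN_S = 0.27
RR_MAX_S = 3.0


@dataclasses.dataclass
class BeatSeries:
    """Detected heart beats: times (s), QRS peak-to-peak amplitudes (mV)."""

    r_peak_times: np.ndarray
    r_peak_to_peak: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.r_peak_times, dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(np.asarray(self.r_peak_to_peak) < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.r_peak_times)


@dataclasses.dataclass
class DerivedSignalSet:
    """The four analysis series on one uniform ``fa`` grid."""

    t: np.ndarray
    edr: np.ndarray
    hrv: np.ndarray
    emge: np.ndarray
    emgi: np.ndarray
    fa: float
    emg_channel: int      # 0-based index of the selected sEMG channel
    ecg_lead: int         # 0-based index of the selected ECG lead
    xcorr: float          # cross-correlation at selection

    def signals(self) -> dict:
        return {"EDR": self.edr, "HRV": self.hrv,
                "EMGe": self.emge, "EMGi": self.emgi}


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins style)
# ---------------------------------------------------------------------------

def _adaptive_threshold(heights: np.ndarray) -> float:
    """Two-means split of log candidate-peak heights.

    Separates the QRS cluster from the noise-peak cluster even under deep
    respiratory amplitude modulation (which widens the QRS cluster).  When
    the two clusters are not meaningfully separated (clean recordings with
    no noise peaks), everything is kept.
    """
    h = np.sort(np.log(np.maximum(heights, 1e-300)))
    n = h.size
    if h[-1] - h[0] < 1e-12:
        return 0.0
    cum = np.cumsum(h)
    k = np.arange(1, n)                     # split: lower h[:k], upper h[k:]
    w0 = k / n
    m0 = cum[:-1] / k
    m1 = (cum[-1] - cum[:-1]) / (n - k)
    between = w0 * (1.0 - w0) * (m0 - m1) ** 2
    best = int(np.argmax(between))
    if m1[best] - m0[best] < np.log(4.0):   # unimodal: keep everything
        return 0.0
    return float(np.exp((h[best] + h[best + 1]) / 2.0))


def detect_r_peaks(ecg_lead: np.ndarray, fs: float = 128.0) -> BeatSeries:
    """Band-pass / differentiate / square / integrate QRS detector.

    R-peak times are refined to the local extremum of the filtered ECG;
    the peak-to-peak amplitude is measured in a +-60 ms window around each
    R peak.  Beats implying RR < 0.27 s or > 3 s are rejected.
    """
    x = np.asarray(ecg_lead, dtype=float)
    if x.size < 10 * fs:
        raise ValueError("need at least 10 s of ECG")
    sos = sps.butter(3, [5.0, 30.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    integ = np.convolve(np.diff(bp, prepend=bp[0]) ** 2,
                        np.ones(int(round(0.15 * fs))), mode="same")
    cand, _ = sps.find_peaks(integ, distance=int(round(RR_MIN_S * fs)))
    if cand.size < 2:
        raise ValueError("insufficient beats")
    locs = cand[integ[cand] > _adaptive_threshold(integ[cand])]
    if locs.size < 2:
        raise ValueError("insufficient beats")

    half = int(round(0.06 * fs))
    times, p2p = [], []
    for loc in locs:
        lo, hi = max(0, loc - half), min(x.size, loc + half + 1)
        seg = x[lo:hi]
        r = lo + int(np.argmax(np.abs(seg)))
        lo2, hi2 = max(0, r - half), min(x.size, r + half + 1)
        seg2 = x[lo2:hi2]
        times.append(r / fs)
        p2p.append(float(seg2.max() - seg2.min()))
    times = np.asarray(times)
    p2p = np.asarray(p2p)

    # drop duplicate refinements then physiologically implausible beats
    keep = np.concatenate([[True], np.diff(times) > 0])
    times, p2p = times[keep], p2p[keep]
    while times.size >= 2:
        rr = np.diff(times)
        bad = np.flatnonzero(rr < RR_MIN_S)
        if bad.size == 0:
            break
        # of each too-close pair, drop the smaller-amplitude beat
        i = bad[0]
        drop = i if p2p[i] < p2p[i + 1] else i + 1
        times = np.delete(times, drop)
        p2p = np.delete(p2p, drop)
    if times.size < 2:
        raise ValueError("insufficient beats")
    return BeatSeries(r_peak_times=times, r_peak_to_peak=p2p)


# ---------------------------------------------------------------------------
# derived series
# ---------------------------------------------------------------------------

def _fa_grid(t0: float, t1: float, fa: float) -> np.ndarray:
    start = np.ceil(t0 * fa) / fa
    n = int(np.floor((t1 - start) * fa)) + 1
    if n < 2:
        raise ValueError("support too short for the analysis grid")
    return start + np.arange(n) / fa


def compute_edr(beats: BeatSeries, fa: float, grid: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """PCHIP interpolation of QRS peak-to-peak amplitudes onto the fa grid.

    Shape-preserving interpolation never overshoots the amplitude range.
    """
    if beats.r_peak_times.size < 4:
        raise ValueError("need at least 4 beats")
    if np.any(np.diff(beats.r_peak_times) <= 0):
        raise ValueError("duplicate beat times")
    f = PchipInterpolator(beats.r_peak_times, beats.r_peak_to_peak)
    if grid is None:
        grid = _fa_grid(beats.r_peak_times[0], beats.r_peak_times[-1], fa)
    return grid, f(grid)


def correct_hrv_outliers(rate: np.ndarray, times: np.ndarray,
                         frac: float = 0.18, max_iter: int | None = None
                         ) -> np.ndarray:
    """Recursive outlier correction of an instantaneous-rate series.

    While any sample deviates from the current series mean by more than
    ``frac`` of the mean, the worst offender is replaced by cubic-spline
    interpolation from the remaining points and the mean is recomputed.
    """
    rate = np.asarray(rate, dtype=float).copy()
    n = rate.size
    max_iter = max_iter if max_iter is not None else 10 * n
    for it in range(max_iter + 1):
        mean = rate.mean()
        dev = np.abs(rate - mean)
        worst = int(np.argmax(dev))
        if dev[worst] <= frac * abs(mean):
            if it:
                logger.info("HRV outlier correction: %d replacements", it)
            return rate
        # interpolate from the currently conforming points; clip to their
        # range so edge extrapolation cannot inject new outliers
        inliers = dev <= frac * abs(mean)
        if inliers.sum() < 4:
            inliers = np.arange(n) != worst
        spline = CubicSpline(times[inliers], rate[inliers])
        rate[worst] = float(np.clip(spline(times[worst]),
                                    rate[inliers].min(), rate[inliers].max()))
    raise RuntimeError("outlier correction diverged")


def compute_hrv(beats: BeatSeries, fa: float, grid: np.ndarray | None = None,
                grid_hz: float = 1.0, outlier_frac: float = 0.18
                ) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous heart rate (1/RR), outlier-corrected and resampled.

    The rate is attached to the second beat of each interval, corrected
    with the recursive 18 %-of-mean rule, cubic-spline interpolated on a
    1 Hz grid and then spline-resampled to ``fa``.
    """
    if beats.r_peak_times.size < 5:
        raise ValueError("need at least 5 beats")
    t = beats.r_peak_times[1:]
    rate = 1.0 / beats.rr_intervals
    rate = correct_hrv_outliers(rate, t, frac=outlier_frac)
    coarse = np.arange(np.ceil(t[0] * grid_hz), np.floor(t[-1] * grid_hz) + 1
                       ) / grid_hz
    s1 = CubicSpline(t, rate)
    on_coarse = s1(coarse)
    if grid is None:
        grid = _fa_grid(coarse[0], coarse[-1], fa)
    s2 = CubicSpline(coarse, on_coarse)
    return grid, s2(np.clip(grid, coarse[0], coarse[-1]))


def compute_emge(semg_ch: np.ndarray, fs: float, fa: float,
                 grid: np.ndarray | None = None, smooth_ms: float = 9.0,
                 polyorder: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """EMG envelope: spline through rectified-signal peaks, then smoothed.

    Local maxima of ``|x|`` are spline-interpolated and smoothed with an
    order-``polyorder`` local least-squares polynomial over a ``smooth_ms``
    window; windows too short for the polynomial (e.g. 9 ms at 128 Hz)
    degrade to a no-op.  The envelope is then sampled on the ``fa`` grid.
    """
    rect = np.abs(np.asarray(semg_ch, dtype=float))
    locs, _ = sps.find_peaks(rect)
    if locs.size < 4:
        raise ValueError("no EMG peaks found")
    spline = CubicSpline(locs / fs, rect[locs])
    t_hi = np.arange(locs[0], locs[-1] + 1) / fs
    env = spline(t_hi)
    win = int(round(smooth_ms * 1e-3 * fs)) | 1
    if win >= polyorder + 2:
        env = sps.savgol_filter(env, win, polyorder)
    else:
        logger.debug("EMGe smoothing window %d samples < order+2; skipped", win)
    # anti-alias before sampling on the fa grid: the peak-spline envelope
    # carries broadband carrier-induced jitter that must not fold into the
    # analysis band
    sos = sps.butter(4, 0.45 * fa, btype="lowpass", fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, env)
    if grid is None:
        grid = _fa_grid(t_hi[0], t_hi[-1], fa)
    return grid, np.interp(np.clip(grid, t_hi[0], t_hi[-1]), t_hi, env)


def compute_emgi(semg_ch: np.ndarray, fs: float, fa: float,
                 grid: np.ndarray | None = None, thresh_quantile: float = 0.70,
                 min_sep_s: float = 0.15) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated supra-threshold EMG peak series.

    Peaks of ``|x|`` above the ``thresh_quantile`` quantile of the rectified
    signal, with an enforced minimum separation of ``min_sep_s`` (the larger
    of two conflicting peaks wins), cubic-spline interpolated to ``fa``.
    """
    rect = np.abs(np.asarray(semg_ch, dtype=float))
    thr = np.quantile(rect, thresh_quantile)
    locs, _ = sps.find_peaks(rect, height=thr,
                             distance=max(int(round(min_sep_s * fs)), 1))
    if locs.size < 4:
        raise ValueError("no supra-threshold EMG peaks found")
    spline = CubicSpline(locs / fs, rect[locs])
    if grid is None:
        grid = _fa_grid(locs[0] / fs, locs[-1] / fs, fa)
    return grid, spline(np.clip(grid, locs[0] / fs, locs[-1] / fs))


# ---------------------------------------------------------------------------
# channel/lead selection and assembly
# ---------------------------------------------------------------------------

def max_xcorr(x: np.ndarray, y: np.ndarray, fa: float,
              max_lag_s: float = 5.0) -> float:
    """Max normalised cross-correlation of z-scored series over +-max_lag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance series")
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    full = np.correlate(xz, yz, mode="full") / x.size
    lags = np.arange(-(x.size - 1), x.size)
    m = np.abs(lags) <= int(round(max_lag_s * fa))
    cc = full[m]
    return float(cc[np.argmax(np.abs(cc))])


def select_channel_pair(emge_all: np.ndarray, edr_all: np.ndarray, fa: float,
                        max_lag_s: float = 5.0) -> tuple[int, int, float]:
    """Pick the (sEMG channel, ECG lead) pair with maximal |cross-corr|.

    ``emge_all``: (5, n) EMGe per channel; ``edr_all``: (3, n) EDR per
    lead, all time-aligned on the ``fa`` grid.  Zero-variance series are
    skipped with a warning.
    """
    best = (-1, -1, 0.0)
    for ch in range(emge_all.shape[0]):
        for lead in range(edr_all.shape[0]):
            try:
                v = max_xcorr(emge_all[ch], edr_all[lead], fa, max_lag_s)
            except ValueError:
                logger.warning("zero-variance series: skipping ch%d/lead%d",
                               ch + 1, lead + 1)
                continue
            if abs(v) > abs(best[2]) or best[0] < 0:
                best = (ch, lead, v)
    if best[0] < 0:
        raise ValueError("no valid channel/lead pair")
    logger.info("selected sEMG ch%d / ECG lead %s (xcorr=%.3f)",
                best[0] + 1, "I II III".split()[best[1]], best[2])
    return best


def derived_signal_snrs(clean: CleanRecording, dset: DerivedSignalSet,
                        cfg: PipelineConfig | None = None) -> dict:
    """Smooth-baseline SNR (dB) of each derived signal, evaluated densely.

    The four series are rebuilt on a 128 Hz grid over the analysis support
    so the baseline model can separate the respiration-scale signal from
    estimator noise (at the 4 Hz analysis rate the two are not
    separable).
    """
    from .preprocess import compute_snr

    cfg = cfg or PipelineConfig()
    fs = clean.fs
    dense = np.arange(dset.t[0], dset.t[-1], 1.0 / fs)
    beats = detect_r_peaks(clean.ecg[dset.ecg_lead], fs)
    _, edr = compute_edr(beats, cfg.fa, grid=dense)
    _, hrv = compute_hrv(beats, cfg.fa, grid=dense, grid_hz=cfg.hrv_grid_hz,
                         outlier_frac=cfg.hrv_outlier_frac)
    _, emge = compute_emge(clean.semg[dset.emg_channel], fs, cfg.fa,
                           grid=dense, smooth_ms=cfg.emge_smooth_ms)
    _, emgi = compute_emgi(clean.semg[dset.emg_channel], fs, cfg.fa,
                           grid=dense, thresh_quantile=cfg.emgi_quantile,
                           min_sep_s=cfg.emgi_min_sep_s)
    return {name: compute_snr(x, fs, cfg.snr_window_s, cfg.snr_polyorder)
            for name, x in (("EDR", edr), ("HRV", hrv), ("EMGe", emge),
                            ("EMGi", emgi))}


def derive_signals(clean: CleanRecording,
                   cfg: PipelineConfig | None = None) -> DerivedSignalSet:
    """Build the four derived series on one common grid and select channels."""
    cfg = cfg or PipelineConfig()
    fa = cfg.fa
    fs = clean.fs

    beats = [detect_r_peaks(clean.ecg[lead], fs) for lead in range(3)]

    # common support: intersection of all sources, then one shared grid
    t0 = max([b.r_peak_times[0] for b in beats]) + 1.0 / cfg.hrv_grid_hz
    t1 = min([b.r_peak_times[-1] for b in beats]) - 1.0 / cfg.hrv_grid_hz
    t0 = max(t0, 0.5)
    t1 = min(t1, clean.duration - 0.5)
    grid = _fa_grid(t0, t1, fa)

    edr_all = np.vstack([compute_edr(b, fa, grid=grid)[1] for b in beats])
    emge_all = np.vstack(
        [compute_emge(clean.semg[ch], fs, fa, grid=grid,
                      smooth_ms=cfg.emge_smooth_ms)[1] for ch in range(5)]
    )
    ch, lead, xc = select_channel_pair(emge_all, edr_all, fa,
                                       cfg.xcorr_max_lag_s)
    _, hrv = compute_hrv(beats[lead], fa, grid=grid,
                         grid_hz=cfg.hrv_grid_hz,
                         outlier_frac=cfg.hrv_outlier_frac)
    _, emgi = compute_emgi(clean.semg[ch], fs, fa, grid=grid,
                           thresh_quantile=cfg.emgi_quantile,
                           min_sep_s=cfg.emgi_min_sep_s)
    dset = DerivedSignalSet(t=grid, edr=edr_all[lead], hrv=hrv,
                            emge=emge_all[ch], emgi=emgi, fa=fa,
                            emg_channel=ch, ecg_lead=lead, xcorr=xc)
    for name, s in dset.signals().items():
        if not np.all(np.isfinite(s)):
            raise ValueError(f"non-finite samples in derived signal {name}")
    return dset
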