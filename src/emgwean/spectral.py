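"""Time-varying Welch spectra, band parameters and magnitude-squared coherence.

Scalar descriptors are extracted per frequency band (LF 0.04-0.15 Hz,
HF 0.15-0.4 Hz) from Hann-tapered Welch estimates:

* ``Hp`` — highest in-band power, ``Fp`` — its frequency,
* ``P``  — total band power (trapezoidal integral),
* ``Us``/``Ds`` — slopes from the band start up to the peak and from the
  peak down to the band end (zero and flagged when the peak sits on a band
  edge; ties broken toward the lowest frequency).

Coherence K(f) = |Sxy|^2 / (Sxx Syy) between the derived-signal pairs is
parameterised the same way, plus its in-band RMS and nearest-bin values at
fixed frequencies (0.02 and 0.04 Hz by default).

The time-varying layer slides a long outer window (default 300 s, 50 %
overlap) over the derived signals; each outer window yields one value per
parameter — a single modified periodogram for the per-signal spectra and a
sub-segmented Welch/MSC estimate (default 60 s sub-segments, 50 % overlap,
9 averages) for the coherences.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal as sps

from .io import PipelineConfig
from .derive import DerivedSignalSet

logger = logging.getLogger("emgwean")

#: canonical coherence pairs (name, first signal, second signal)
COHERENCE_PAIRS = (
    ("EDREMGe", "EMGe", "EDR"),
    ("HRVEMGe", "EMGe", "HRV"),
    ("EDREMGi", "EMGi", "EDR"),
    ("HRVEMGi", "EMGi", "HRV"),
)

#: extra pairs reported in some analyses; excluded from the canonical catalog
EXTRA_PAIRS = (("EMGiEMGe", "EMGe", "EMGi"),)


@dataclasses.dataclass
class PsdEstimate:
    frequencies: np.ndarray
    power: np.ndarray
    n_segments: int
    seg_len_s: float
    overlap: float
    taper: str = "hann"


@dataclasses.dataclass
class BandParams:
    hp: float
    fp: float
    p: float
    us: float
    ds: float
    band: tuple
    edge_peak: bool = False     # Fp fell on a band edge; slopes zeroed

    def as_dict(self, prefix: str = "", suffix: str = "") -> dict:
        return {f"{prefix}Hp{suffix}": self.hp, f"{prefix}P{suffix}": self.p,
                f"{prefix}Fp{suffix}": self.fp, f"{prefix}Us{suffix}": self.us,
                f"{prefix}Ds{suffix}": self.ds}


@dataclasses.dataclass
class ParamSeries:
    """One named parameter sampled once per analysis window."""

    name: str
    window_starts: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.window_starts) <= 0):
            raise ValueError("window start times must increase")


def n_segments(n: int, nperseg: int, noverlap: int) -> int:
    if n < nperseg:
        return 0
    step = nperseg - noverlap
    return 1 + (n - nperseg) // step


def welch_psd(x: np.ndarray, fa: float, seg_len_s: float,
              overlap: float = 0.5) -> PsdEstimate:
    """Hann-tapered, mean-removed, density-normalised Welch PSD."""
    x = np.asarray(x, dtype=float)
    nper = int(round(seg_len_s * fa))
    if x.size < nper:
        raise ValueError("series shorter than one segment")
    nov = int(round(overlap * nper))
    f, pxx = sps.welch(x, fs=fa, window="hann", nperseg=nper, noverlap=nov,
                       detrend="constant", scaling="density")
    return PsdEstimate(frequencies=f, power=pxx,
                       n_segments=n_segments(x.size, nper, nov),
                       seg_len_s=seg_len_s, overlap=overlap)


def band_parameters(freqs: np.ndarray, power: np.ndarray,
                    band: tuple) -> BandParams:
    """Hp/Fp/P/Us/Ds descriptors of a spectrum restricted to ``band``.

    Band edges belong to the band (closed interval).  ``P`` is the
    trapezoidal integral over the in-band grid.  Slopes are computed
    against the spectrum values at the first and last in-band bins; if the
    peak sits on a band edge the corresponding slopes are zero and flagged.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    f_lo, f_hi = band
    m = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    if m.sum() < 3:
        raise ValueError("fewer than 3 bins in band")
    fb, pb = freqs[m], power[m]
    i = int(np.argmax(pb))          # first occurrence = lowest frequency
    hp, fp = float(pb[i]), float(fb[i])
    p = float(np.trapezoid(pb, fb))
    edge = i == 0 or i == pb.size - 1
    us = 0.0 if i == 0 else float((hp - pb[0]) / (fp - fb[0]))
    ds = 0.0 if i == pb.size - 1 else float((pb[-1] - hp) / (fb[-1] - fp))
    return BandParams(hp=hp, fp=fp, p=p, us=us, ds=ds, band=tuple(band),
                      edge_peak=edge)


def msc(x: np.ndarray, y: np.ndarray, fa: float, seg_len_s: float,
        overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch-averaged magnitude-squared coherence, clipped to [0, 1].

    Requires at least 4 averaged segments (with a single segment the
    estimate is identically 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series lengths differ")
    nper = int(round(seg_len_s * fa))
    nov = int(round(overlap * nper))
    if n_segments(x.size, nper, nov) < 4:
        raise ValueError("insufficient segments for coherence")
    f, k = sps.coherence(x, y, fs=fa, window="hann", nperseg=nper,
                         noverlap=nov, detrend="constant")
    if np.any(k < -1e-12) or np.any(k > 1 + 1e-12):
        raise AssertionError("coherence outside [0,1] beyond round-off")
    return f, np.clip(k, 0.0, 1.0)


def coherence_parameters(freqs: np.ndarray, k: np.ndarray, band: tuple,
                         fixed_freqs: tuple = (0.02, 0.04)) -> dict:
    """Band descriptors of a coherence spectrum plus fixed-frequency values.

    Returns ``Pcoh``/``RMScoh``/``Fpcoh``/``Hpcoh``/``Uscoh``/``Dscoh`` and
    one nearest-bin ``Hpcoh(j)`` entry per fixed frequency (looked up on
    the full-range grid).
    """
    bp = band_parameters(freqs, k, band)
    fb = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    out = {"Pcoh": bp.p, "RMScoh": float(np.sqrt(np.mean(k[fb] ** 2))),
           "Fpcoh": bp.fp, "Hpcoh": bp.hp, "Uscoh": bp.us, "Dscoh": bp.ds}
    for j in fixed_freqs:
        if j < freqs[0] - 1e-12 or j > freqs[-1] + 1e-12:
            raise ValueError(f"fixed frequency {j} Hz outside the grid")
        out[f"Hpcoh_{j:g}Hz"] = float(k[np.argmin(np.abs(freqs - j))])
    return out


# ---------------------------------------------------------------------------
# time-varying layer
# ---------------------------------------------------------------------------

def iter_windows(n: int, fa: float, window_s: float, overlap: float):
    """Half-open sliding windows [i0, i0+L) over an n-sample fa-grid."""
    length = int(round(window_s * fa))
    step = int(round(length * (1.0 - overlap)))
    if step < 1 or length > n:
        return
    for i0 in range(0, n - length + 1, step):
        yield i0, i0 + length


def windowed_params(dset: DerivedSignalSet,
                    cfg: PipelineConfig | None = None,
                    include_extra_pairs: bool = False) -> dict:
    """Per-window spectral and coherence parameters for all derived signals.

    Returns a dict name -> :class:`ParamSeries` with 40 spectral entries
    ({Hp,P,Fp,Us,Ds} x {LF,HF} x 4 signals) and 32 coherence entries
    ({Pcoh,RMScoh,Fpcoh,Hpcoh,Uscoh,Dscoh} x 4 pairs + Hpcoh(j) at 2 fixed
    frequencies x 4 pairs).
    """
    cfg = cfg or PipelineConfig()
    sigs = dset.signals()
    bands = {"LF": tuple(cfg.lf_band), "HF": tuple(cfg.hf_band)}
    pairs = COHERENCE_PAIRS + (EXTRA_PAIRS if include_extra_pairs else ())

    windows = list(iter_windows(dset.t.size, dset.fa, cfg.window_s,
                                cfg.overlap))
    if len(windows) < 2:
        raise ValueError("recording shorter than two outer analysis windows")
    starts = np.array([dset.t[i0] for i0, _ in windows])

    acc: dict[str, list] = {}
    for i0, i1 in windows:
        # one modified periodogram per signal over the whole outer window
        for name, x in sigs.items():
            est = welch_psd(x[i0:i1], dset.fa,
                            seg_len_s=(i1 - i0) / dset.fa, overlap=0.0)
            for bname, band in bands.items():
                bp = band_parameters(est.frequencies, est.power, band)
                for key, val in bp.as_dict(suffix=f"{bname}{name}").items():
                    acc.setdefault(key, []).append(val)
        # sub-segmented coherence per pair (HF band hosts the descriptors;
        # fixed-frequency lookups come from the full-range grid)
        for pname, a, b in pairs:
            f, k = msc(sigs[a][i0:i1], sigs[b][i0:i1], dset.fa,
                       seg_len_s=cfg.sub_window_s, overlap=cfg.sub_overlap)
            cp = coherence_parameters(f, k, tuple(cfg.hf_band),
                                      tuple(cfg.coh_fixed_freqs))
            for key, val in cp.items():
                if "_" in key:                      # Hpcoh_0.02Hz style
                    base, j = key.split("_", 1)
                    out_key = f"{base}{pname}_{j}"
                else:
                    out_key = f"{key}{pname}"
                acc.setdefault(out_key, []).append(val)

    return {name: ParamSeries(name=name, window_starts=starts,
                              values=np.asarray(vals))
            for name, vals in acc.items()}
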