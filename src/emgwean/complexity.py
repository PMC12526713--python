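"""Approximate and sample entropy of the derived signals.

Both statistics use Chebyshev (max-component) template matching with
embedding length ``m`` (default 2) and tolerance ``r`` expressed as a
multiple (default 0.15) of the analysed window's sample standard
deviation:

* ``ApEn`` (Pincus) counts matches *including* each template against
  itself, so it is always finite: ApEn = Phi_m - Phi_{m+1}, with Phi_k the
  mean log relative match frequency of the k-length templates.
* ``SampEn`` excludes self-matches and is the negative log of the
  conditional probability that templates matching for m points still match
  at m+1: SampEn = -log(A/B).  When no m- or (m+1)-matches exist the value
  is undefined and reported as NaN.

The time-varying layer evaluates both statistics per outer analysis window
(r recomputed from each window's SD), yielding one parameter series per
(statistic, signal) combination.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io import PipelineConfig
from .derive import DerivedSignalSet
from .spectral import ParamSeries, iter_windows

logger = logging.getLogger("emgwean")


@dataclasses.dataclass
class EntropyConfig:
    m: int = 2
    r_mult: float = 0.15

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("embedding length m must be >= 1")
        if self.r_mult <= 0:
            raise ValueError("tolerance multiplier must be positive")


def _cheb_dist(x: np.ndarray, m: int) -> np.ndarray:
    """Pairwise Chebyshev distances between all length-m templates.

    Built component-wise with in-place maxima so only (n, n) scratch is
    needed, never an (n, n, m) tensor.
    """
    n_t = x.size - m + 1
    d = np.abs(x[:n_t, None] - x[None, :n_t])
    for k in range(1, m):
        np.maximum(d, np.abs(x[k:k + n_t, None] - x[None, k:k + n_t]), out=d)
    return d


def apen(x: np.ndarray, m: int, r_abs: float) -> float:
    """Approximate entropy with self-counting (always finite)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError("series too short for the embedding length")
    if r_abs <= 0:
        raise ValueError("tolerance must be positive")

    def phi(k):
        counts = (_cheb_dist(x, k) <= r_abs).sum(axis=1)
        return np.mean(np.log(counts / (n - k + 1)))

    return float(phi(m) - phi(m + 1))


def sampen(x: np.ndarray, m: int, r_abs: float) -> float:
    """Sample entropy (self-matches excluded); NaN when undefined.

    A and B count (m+1)- and m-template pairs within tolerance among the
    first N-m templates, so both are drawn from the same template set.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError("series too short for the embedding length")
    if r_abs <= 0:
        raise ValueError("tolerance must be positive")
    a, b = _sampen_counts(x, m, r_abs)
    if b == 0 or a == 0:
        logger.info("sampen undefined (A=%d, B=%d)", a, b)
        return float("nan")
    return float(-np.log(a / b))


def _sampen_counts(x, m, r_abs):
    n = x.size
    dm = _cheb_dist(x, m)[: n - m, : n - m]
    dm1 = _cheb_dist(x, m + 1)
    b = (int((dm <= r_abs).sum()) - (n - m)) // 2
    a = (int((dm1 <= r_abs).sum()) - (n - m)) // 2
    return a, b


def windowed_entropy(dset: DerivedSignalSet,
                     cfg: PipelineConfig | None = None,
                     min_window_samples: int = 100) -> dict:
    """SampEn/ApEn per outer window for each of the four derived signals.

    ``r`` is recomputed per window as ``r_mult`` times that window's sample
    standard deviation.  Returns 8 :class:`ParamSeries`; windows where
    SampEn is undefined carry NaN (excluded from downstream summaries).
    """
    cfg = cfg or PipelineConfig()
    ecfg = EntropyConfig(m=cfg.entropy_m, r_mult=cfg.entropy_r_mult)
    windows = list(iter_windows(dset.t.size, dset.fa, cfg.window_s,
                                cfg.overlap))
    if len(windows) < 2:
        raise ValueError("recording shorter than two outer analysis windows")
    if any(i1 - i0 < min_window_samples for i0, i1 in windows):
        raise ValueError("analysis window shorter than the entropy minimum")
    starts = np.array([dset.t[i0] for i0, _ in windows])

    out = {}
    n_undef = 0
    for name, x in dset.signals().items():
        se, ae = [], []
        for i0, i1 in windows:
            w = x[i0:i1]
            r = ecfg.r_mult * float(np.std(w, ddof=1))
            if r <= 0:
                se.append(np.nan)
                ae.append(0.0)      # constant window: perfectly regular
                continue
            s = sampen(w, ecfg.m, r)
            n_undef += int(np.isnan(s))
            se.append(s)
            ae.append(apen(w, ecfg.m, r))
        out[f"SampEn{name}"] = ParamSeries(f"SampEn{name}", starts,
                                           np.asarray(se))
        out[f"ApEn{name}"] = ParamSeries(f"ApEn{name}", starts,
                                         np.asarray(ae))
    if n_undef:
        logger.info("windowed_entropy: %d undefined SampEn windows", n_undef)
    return out
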