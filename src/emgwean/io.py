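"""Data model and I/O for weaning-trial recordings and feature tables.

A :class:`Recording` holds one patient's raw 3-lead ECG (128 Hz) and
5-channel diaphragm sEMG (1 kHz).  Recordings are stored either as EDF
(European Data Format, the de-facto standard for polysomnography/EMG) or as
a delimited text file pair with a JSON sidecar.  Feature matrices are plain
CSV tables (one row per patient).

Channel order is canonical and never permuted on re-read:
ECG leads I, II, III then sEMG channels Ch1..Ch5.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("emgwean")

GROUPS = ("success", "failure", "unknown")

ECG_LABELS = ("ECG I", "ECG II", "ECG III")
EMG_LABELS = ("EMG Ch1", "EMG Ch2", "EMG Ch3", "EMG Ch4", "EMG Ch5")

#: token used for non-finite feature values in delimited tables
MISSING_TOKEN = ""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Recording:
    """One patient's raw multichannel recording.

    Parameters
    ----------
    patient_id : str
    group : {"success", "failure", "unknown"}
        Weaning outcome label.
    ecg : ndarray, shape (3, n_ecg)
        Leads I, II, III in mV at ``fs_ecg``.
    semg : ndarray, shape (5, n_emg)
        Diaphragm surface EMG channels Ch1..Ch5 in mV at ``fs_emg``.
    """

    patient_id: str
    group: str
    ecg: np.ndarray
    semg: np.ndarray
    fs_ecg: float = 128.0
    fs_emg: float = 1000.0
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.ecg = np.atleast_2d(np.asarray(self.ecg, dtype=float))
        self.semg = np.atleast_2d(np.asarray(self.semg, dtype=float))
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.ecg.shape[0] != 3:
            raise ValueError("expected 3 ECG leads")
        if self.semg.shape[0] != 5:
            raise ValueError("expected 5 sEMG channels")
        if self.fs_ecg <= 0 or self.fs_emg <= 0:
            raise ValueError("sampling rates must be strictly positive")
        # duration consistency within one sample
        d_ecg = self.ecg.shape[1] / self.fs_ecg
        d_emg = self.semg.shape[1] / self.fs_emg
        if abs(d_ecg - d_emg) > max(1.0 / self.fs_ecg, 1.0 / self.fs_emg):
            raise ValueError(
                f"ECG ({d_ecg:.3f}s) and sEMG ({d_emg:.3f}s) durations disagree"
            )

    @property
    def duration(self) -> float:
        """Recording length in seconds (from the ECG channel)."""
        return self.ecg.shape[1] / self.fs_ecg


@dataclasses.dataclass
class PipelineConfig:
    """All tunable constants of the analysis pipeline.

    Defaults follow standard short-term cardiorespiratory practice: 60 Hz
    mains notch, 0.05 Hz (ECG) / 20 Hz (sEMG) high-pass cutoffs, LF
    0.04-0.15 Hz and HF 0.15-0.4 Hz bands, 300 s analysis windows with 50 %
    overlap, entropy with m=2 and r=0.15*SD, raw-alpha 0.05 significance and
    Spearman |rho|<0.6 selection, degree-5 polynomial SVM, 1000 evaluation
    runs.
    """

    # preprocessing
    notch_hz: float = 60.0
    notch_q: float = 35.0
    hp_ecg_hz: float = 0.05
    hp_emg_hz: float = 20.0
    filter_order: int = 4
    despike_z: float = 8.0
    snr_window_s: float = 0.5
    snr_polyorder: int = 3
    # derived signals
    fa: float = 4.0                # common analysis rate, Hz
    hrv_grid_hz: float = 1.0       # native HRV interpolation rate
    hrv_outlier_frac: float = 0.18
    emgi_quantile: float = 0.70
    emgi_min_sep_s: float = 0.15
    emge_smooth_ms: float = 9.0
    xcorr_max_lag_s: float = 5.0
    # time-varying windowing
    window_s: float = 300.0
    overlap: float = 0.5
    sub_window_s: float = 60.0
    sub_overlap: float = 0.5
    # bands
    lf_band: tuple = (0.04, 0.15)
    hf_band: tuple = (0.15, 0.4)
    coh_fixed_freqs: tuple = (0.02, 0.04)
    # entropy
    entropy_m: int = 2
    entropy_r_mult: float = 0.15
    # selection
    alpha: float = 0.05
    rho_max: float = 0.6
    # classification
    svm_degree: int = 5
    svm_c: float = 1.0
    knn_k: int = 5
    knn_metric: str = "spearman"
    n_runs: int = 1000
    train_frac: float = 0.7
    elim_runs: int = 100
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not 0.0 < self.overlap < 1.0 or not 0.0 < self.sub_overlap < 1.0:
            raise ValueError("overlap fractions must lie in (0, 1)")
        lf, hf = tuple(self.lf_band), tuple(self.hf_band)
        if not (lf[0] < lf[1] <= hf[0] < hf[1]):
            raise ValueError("LF and HF bands must be ordered and non-overlapping")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.rho_max <= 1.0:
            raise ValueError("rho_max must be in (0, 1]")
        if self.fa < 2.0 * hf[1]:
            raise ValueError("analysis rate fa must be at least twice the HF edge")
        if self.entropy_m < 1 or self.entropy_r_mult <= 0:
            raise ValueError("entropy settings invalid")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a flat JSON key/value file; unknown keys are rejected."""
        raw = json.loads(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lf_band", "hf_band", "coh_fixed_freqs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path):
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=list))


# ---------------------------------------------------------------------------
# EDF read/write (16-bit, 1-second data records)
# ---------------------------------------------------------------------------

def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def _fmt8(v: float) -> str:
    """Shortest %g representation of v that fits an 8-char EDF field."""
    for p in range(8, 0, -1):
        s = f"{v:.{p}g}"
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot represent {v} in 8 characters")


def write_recording(rec: Recording, path, fmt: str = "edf") -> None:
    """Write a :class:`Recording` to ``path`` as EDF or a delimited file set."""
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "delimited":
        _write_delimited(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    logger.info("wrote recording %s (%s) to %s", rec.patient_id, fmt, path)


def read_recording(path, fmt: str = "edf") -> Recording:
    """Read a :class:`Recording` written by :func:`write_recording`.

    Channels are returned in canonical order (leads I-III then Ch1-Ch5);
    sampling rates come from the EDF header or the JSON sidecar.
    """
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown format {fmt!r}")


def _write_edf(rec: Recording, path) -> None:
    fs_ecg, fs_emg = rec.fs_ecg, rec.fs_emg
    if abs(fs_ecg - round(fs_ecg)) > 1e-9 or abs(fs_emg - round(fs_emg)) > 1e-9:
        raise ValueError("EDF writer requires integer sampling rates")
    spr = [int(round(fs_ecg))] * 3 + [int(round(fs_emg))] * 5  # samples/record
    n_rec = int(np.floor(rec.duration + 1e-9))
    if n_rec < 1:
        raise ValueError("recording shorter than one 1-s EDF record")
    chans = [rec.ecg[i, : n_rec * spr[i]] for i in range(3)]
    chans += [rec.semg[i, : n_rec * spr[3 + i]] for i in range(5)]
    labels = list(ECG_LABELS) + list(EMG_LABELS)

    pmins, pmaxs, digital = [], [], []
    for x in chans:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo <= 0:
            lo, hi = lo - 1.0, hi + 1.0
        # quantise against the physical min/max exactly as they survive the
        # 8-char header fields, so the round-trip error is the 16-bit bound
        margin = 1e-3 * (hi - lo)
        while True:
            slo, shi = _fmt8(lo - margin), _fmt8(hi + margin)
            plo, phi = float(slo), float(shi)
            if plo <= lo and phi >= hi and phi > plo:
                break
            margin *= 2.0
        scale = (phi - plo) / 65535.0
        dig = np.round((x - plo) / scale - 32768.0).astype("<i2")
        pmins.append(slo)
        pmaxs.append(shi)
        digital.append(dig)

    ns = 8
    header = bytearray()
    header += _pad("0", 8)
    header += _pad(rec.patient_id, 80)
    header += _pad(f"group={rec.group}", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (ns + 1)), 8)
    header += _pad("", 44)
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)
    header += _pad(str(ns), 4)
    for lab in labels:
        header += _pad(lab, 16)
    header += _pad("", 80) * ns                       # transducer
    header += b"".join(_pad("mV", 8) for _ in range(ns))
    header += b"".join(_pad(s, 8) for s in pmins)
    header += b"".join(_pad(s, 8) for s in pmaxs)
    header += _pad("-32768", 8) * ns
    header += _pad("32767", 8) * ns
    header += _pad("", 80) * ns                       # prefiltering
    header += b"".join(_pad(str(s), 8) for s in spr)
    header += _pad("", 32) * ns

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            for c in range(ns):
                seg = digital[c][r * spr[c] : (r + 1) * spr[c]]
                fh.write(seg.tobytes())


def _read_edf(path) -> Recording:
    with open(path, "rb") as fh:
        head = fh.read(256)
        patient_id = head[8:88].decode("ascii").strip()
        rec_field = head[88:168].decode("ascii").strip()
        n_rec = int(head[236:244].decode("ascii").strip())
        rec_dur = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * ns)

        def field(offset, width):
            start = offset * ns
            return [
                sig[start + i * width : start + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = field(0, 16)
        pmins = [float(v) for v in field(16 + 80 + 8, 8)]
        pmaxs = [float(v) for v in field(16 + 80 + 8 + 8, 8)]
        dmins = [float(v) for v in field(16 + 80 + 8 + 16, 8)]
        dmaxs = [float(v) for v in field(16 + 80 + 8 + 24, 8)]
        spr = [int(v) for v in field(16 + 80 + 8 + 32 + 80, 8)]
        data = np.frombuffer(fh.read(), dtype="<i2")

    per_rec = sum(spr)
    if data.size < per_rec * n_rec:
        raise ValueError("EDF data section truncated")
    data = data[: per_rec * n_rec].reshape(n_rec, per_rec)
    offs = np.concatenate([[0], np.cumsum(spr)])
    physical = []
    for c in range(ns):
        dig = data[:, offs[c] : offs[c + 1]].reshape(-1).astype(float)
        gain = (pmaxs[c] - pmins[c]) / (dmaxs[c] - dmins[c])
        physical.append(pmins[c] + (dig - dmins[c]) * gain)

    ecg_idx = [i for i, l in enumerate(labels) if l.upper().startswith("ECG")]
    emg_idx = [i for i, l in enumerate(labels) if l.upper().startswith("EMG")]
    if len(ecg_idx) < 3 or len(emg_idx) < 5:
        raise ValueError("channel set incomplete")
    ecg_idx = sorted(ecg_idx, key=lambda i: list(ECG_LABELS).index(labels[i])
                     if labels[i] in ECG_LABELS else i)[:3]
    emg_idx = sorted(emg_idx, key=lambda i: list(EMG_LABELS).index(labels[i])
                     if labels[i] in EMG_LABELS else i)[:5]

    group = "unknown"
    if "group=" in rec_field:
        cand = rec_field.split("group=")[1].split()[0]
        if cand in GROUPS:
            group = cand
    return Recording(
        patient_id=patient_id,
        group=group,
        ecg=np.vstack([physical[i] for i in ecg_idx]),
        semg=np.vstack([physical[i] for i in emg_idx]),
        fs_ecg=spr[ecg_idx[0]] / rec_dur,
        fs_emg=spr[emg_idx[0]] / rec_dur,
    )


# ---------------------------------------------------------------------------
# delimited read/write (CSV pair + JSON sidecar; exact round-trip)
# ---------------------------------------------------------------------------

def _delimited_paths(base):
    base = Path(base)
    stem = base.parent / base.name
    return (
        stem.with_name(stem.name + "_ecg.csv"),
        stem.with_name(stem.name + "_emg.csv"),
        stem.with_name(stem.name + "_meta.json"),
    )


def _write_delimited(rec: Recording, base) -> None:
    p_ecg, p_emg, p_meta = _delimited_paths(base)
    pd.DataFrame(rec.ecg.T, columns=["lead_I", "lead_II", "lead_III"]).to_csv(
        p_ecg, index=False, float_format="%.17g"
    )
    pd.DataFrame(rec.semg.T, columns=[f"ch{i}" for i in range(1, 6)]).to_csv(
        p_emg, index=False, float_format="%.17g"
    )
    meta = {
        "patient_id": rec.patient_id,
        "group": rec.group,
        "fs_ecg": rec.fs_ecg,
        "fs_emg": rec.fs_emg,
        "meta": rec.meta,
    }
    p_meta.write_text(json.dumps(meta, indent=2))


def _read_delimited(base) -> Recording:
    p_ecg, p_emg, p_meta = _delimited_paths(base)
    for p in (p_ecg, p_emg, p_meta):
        if not p.exists():
            raise FileNotFoundError(p)
    ecg = pd.read_csv(p_ecg, float_precision="round_trip")
    emg = pd.read_csv(p_emg, float_precision="round_trip")
    if ecg.shape[1] < 3 or emg.shape[1] < 5:
        raise ValueError("channel set incomplete")
    meta = json.loads(p_meta.read_text())
    return Recording(
        patient_id=meta["patient_id"],
        group=meta["group"],
        ecg=ecg.to_numpy().T[:3],
        semg=emg.to_numpy().T[:5],
        fs_ecg=meta["fs_ecg"],
        fs_emg=meta["fs_emg"],
        meta=meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_features(matrix: pd.DataFrame, path) -> None:
    """Write a patients x features table to CSV.

    ``matrix`` must carry ``patient_id`` and ``group`` columns; non-finite
    feature values are stored as an empty missing token and round-trip to
    NaN.  Duplicate feature names are rejected.
    """
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dupes}")
    for col in ("patient_id", "group"):
        if col not in matrix.columns:
            raise ValueError(f"feature matrix must carry a {col!r} column")
    matrix.to_csv(path, index=False, na_rep=MISSING_TOKEN, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    """Exact inverse of :func:`write_features` (missing token -> NaN)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "group": str},
                     float_precision="round_trip")
    return df
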