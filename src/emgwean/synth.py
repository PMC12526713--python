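"""Synthetic two-group cohort generator.

Emulates the measurement setting of a spontaneous-breathing-trial study:
3-lead ECG at 128 Hz and 5-channel diaphragm sEMG at 1 kHz, recorded for
about an hour per patient.  The generator is deliberately minimal — it only
reproduces the statistical structure the downstream analysis consumes:

* a QRS-like wavelet train whose beat-to-beat intervals carry LF and HF
  (respiratory) modulation, and whose peak-to-peak amplitude is modulated at
  the respiratory rate (the ECG-derived-respiration substrate);
* broadband (20-450 Hz) diaphragm EMG bursts locked to the shared
  respiratory phase, channel 3 carrying the strongest locking;
* group contrasts matching the reported physiology of weaning outcome:
  successful patients show a deeper ECG-derived respiration modulation,
  stronger cardio-diaphragmatic coupling and more irregular (higher-entropy)
  burst trains; failing patients show higher EMG amplitude, a faster
  respiratory rate and more stereotyped bursts.

It does not attempt biophysically realistic ECG morphology (no P/T waves),
motion artifacts or electrode modeling.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .io import Recording

logger = logging.getLogger("emgwean")


#: base parameters whose group contrast the generator establishes by
#: construction (EMG amplitude -> HF band power; EDR modulation depth ->
#: EDR band power/peak; tonic-activity irregularity -> EMG entropies;
#: respiratory-phase coupling -> EMGe coherences).  Their per-patient mean
#: statistics are the designed-informative features.
DESIGNED_INFORMATIVE = (
    "PHFEMGe", "PHFEMGi", "PHFEDR", "HpHFEDR",
    "SampEnEMGe", "ApEnEMGe", "SampEnEMGi",
    "PcohEDREMGe", "RMScohEDREMGe", "RMScohHRVEMGe",
)


@dataclasses.dataclass
class GroupParams:
    """Per-outcome-group contrast parameters."""

    resp_rate_hz: float          # mean breathing rate
    edr_depth: float             # QRS amplitude modulation depth (0..1)
    emg_amp_mv: float            # EMG burst amplitude
    emg_irregularity: float      # relative burst-to-burst amplitude jitter
    coupling: float              # resp-phase locking of EMG bursts (0..1)

    def validate(self):
        if not 0.0 <= self.edr_depth < 1.0:
            raise ValueError("edr_depth must be in [0, 1)")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if self.emg_amp_mv <= 0 or self.resp_rate_hz <= 0:
            raise ValueError("amplitudes and rates must be positive")


def _default_success():
    # success: deeper EDR modulation, stronger coupling, more irregular
    # bursts, lower EMG amplitude, ~18.7 breaths/min
    return GroupParams(resp_rate_hz=0.31, edr_depth=0.45, emg_amp_mv=0.015,
                       emg_irregularity=0.50, coupling=0.90)


def _default_failure():
    # failure: elevated EMG amplitude, shallower EDR, weaker coupling,
    # stereotyped bursts, ~21.2 breaths/min
    return GroupParams(resp_rate_hz=0.35, edr_depth=0.15, emg_amp_mv=0.035,
                       emg_irregularity=0.20, coupling=0.50)


@dataclasses.dataclass
class CohortSpec:
    """Study-condition parameters for one synthetic cohort."""

    n_success: int = 19
    n_failure: int = 21
    duration: float = 3600.0          # seconds per recording
    fs_ecg: float = 128.0
    fs_emg: float = 1000.0
    mean_rr: float = 0.8              # seconds per beat (75 bpm)
    rr_lf_depth: float = 0.05         # LF (Mayer-wave) RR modulation
    rr_lf_hz: float = 0.10
    rr_hf_depth: float = 0.04         # respiratory sinus arrhythmia
    rr_jitter: float = 0.01           # white RR jitter, fraction of mean RR
    resp_jitter: float = 0.03         # relative respiratory frequency drift
    ecg_amp_mv: float = 1.0
    snr_ecg_db: float = 21.0
    snr_emg_db: float = 14.0
    analysis_rate_hz: float = 4.0     # downstream derived-signal rate
    success: GroupParams = dataclasses.field(default_factory=_default_success)
    failure: GroupParams = dataclasses.field(default_factory=_default_failure)
    seed: int = 0

    def __post_init__(self):
        if self.n_success < 0 or self.n_failure < 0:
            raise ValueError("group sizes must be non-negative")
        if not 0.0 <= self.rr_lf_depth < 1.0 or not 0.0 <= self.rr_hf_depth < 1.0:
            raise ValueError("RR modulation depths must be in [0, 1)")
        for gp in (self.success, self.failure):
            gp.validate()
            if gp.resp_rate_hz >= self.analysis_rate_hz / 2.0:
                raise ValueError(
                    "respiratory rate at or above the Nyquist of the "
                    "derived-signal analysis rate"
                )

    def group_params(self, group: str) -> GroupParams:
        if group == "success":
            return self.success
        if group == "failure":
            return self.failure
        raise ValueError(f"unknown group {group!r}")


# ---------------------------------------------------------------------------
# respiratory phase (shared between ECG and sEMG of one patient)
# ---------------------------------------------------------------------------

_PHASE_FS = 8.0  # Hz, internal phase-grid rate


def make_resp_phase(duration, f_resp, jitter, rng):
    """Slowly frequency-jittered respiratory phase.

    Returns ``(t, phi)`` where ``phi`` is the unwrapped phase in radians on
    an 8 Hz grid; evaluate elsewhere with ``np.interp``.
    """
    n = int(np.ceil(duration * _PHASE_FS)) + 1
    drift = rng.standard_normal(n)
    drift = gaussian_filter1d(drift, sigma=10.0 * _PHASE_FS, mode="reflect")
    sd = drift.std()
    if sd > 0:
        drift /= sd
    f_inst = f_resp * (1.0 + jitter * drift)
    phi = 2.0 * np.pi * np.cumsum(f_inst) / _PHASE_FS
    phi += rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / _PHASE_FS
    return t, phi


def _eval_phase(phase, t):
    pt, phi = phase
    return np.interp(t, pt, phi)


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

_LEAD_GAINS = (0.70, 1.00, 0.85)        # leads I, II, III
_LEAD_EDR_GAINS = (0.60, 1.00, 0.80)    # lead II carries the strongest EDR
# respiration-unrelated beat-to-beat amplitude jitter (electrical-axis
# variability), weakest on lead II: makes its EDR the cleanest
_LEAD_AMP_JITTER = (0.25, 0.05, 0.15)

# Mexican-hat width; ~80-100 ms QRS support, spectral peak near 11 Hz so
# the complex is well represented at the 128 Hz ECG rate
_QRS_SIGMA_S = 0.020


def _qrs_wavelet(fs):
    half = int(round(4 * _QRS_SIGMA_S * fs))
    t = np.arange(-half, half + 1) / fs
    u = (t / _QRS_SIGMA_S) ** 2
    w = (1.0 - u) * np.exp(-u / 2.0)
    return w / (w.max() - w.min())       # unit peak-to-peak


def _beat_times(spec: CohortSpec, phase, rng):
    beats = [0.3 + 0.4 * rng.random()]
    while True:
        t = beats[-1]
        rr = spec.mean_rr * (
            1.0
            + spec.rr_lf_depth * np.sin(2.0 * np.pi * spec.rr_lf_hz * t)
            + spec.rr_hf_depth * np.sin(_eval_phase(phase, t))
            + spec.rr_jitter * rng.standard_normal()
        )
        rr = float(np.clip(rr, 0.3, 2.5))
        if t + rr > spec.duration - 0.2:
            break
        beats.append(t + rr)
    return np.asarray(beats)


def generate_ecg(spec: CohortSpec, group: str, rng, phase=None,
                 return_components=False):
    """Generate the 3 ECG leads (mV, 128 Hz) for one patient.

    The QRS train follows an RR process with LF and respiratory (HF)
    modulation; QRS amplitude is modulated at the respiratory rate with the
    group's EDR depth.  Band-limited noise is added at ``spec.snr_ecg_db``.
    """
    gp = spec.group_params(group)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if phase is None:
        phase = make_resp_phase(spec.duration, gp.resp_rate_hz,
                                spec.resp_jitter, rng)
    fs = spec.fs_ecg
    n = int(round(spec.duration * fs))
    beats = _beat_times(spec, phase, rng)
    wav = _qrs_wavelet(fs)
    half = (len(wav) - 1) // 2
    mod = 1.0 + np.outer(np.asarray(_LEAD_EDR_GAINS) * gp.edr_depth,
                         np.sin(_eval_phase(phase, beats)))  # (3, nbeats)
    clean = np.zeros((3, n))
    idx0 = np.round(beats * fs).astype(int)
    for lead in range(3):
        jitter = 1.0 + _LEAD_AMP_JITTER[lead] * rng.standard_normal(
            beats.size)
        amps = spec.ecg_amp_mv * _LEAD_GAINS[lead] * mod[lead] * \
            np.maximum(jitter, 0.2)
        for i0, a in zip(idx0, amps):
            lo, hi = i0 - half, i0 + half + 1
            wlo, whi = max(0, -lo), len(wav) - max(0, hi - n)
            clean[lead, max(0, lo):min(n, hi)] += a * wav[wlo:whi]

    sos = sps.butter(4, [0.5, 40.0], btype="bandpass", fs=fs, output="sos")
    noise = np.empty_like(clean)
    # amplifier/electrode noise is absolute, not proportional: one common
    # noise power (set against the reference lead II) across all leads, so
    # the largest-amplitude lead also carries the cleanest EDR
    p_noise = np.var(clean[1]) * 10.0 ** (-spec.snr_ecg_db / 10.0)
    for lead in range(3):
        w = sps.sosfilt(sos, rng.standard_normal(n))
        noise[lead] = w * np.sqrt(p_noise / np.var(w))
    out = clean + noise
    if return_components:
        return out, clean, noise
    return out


# ---------------------------------------------------------------------------
# sEMG
# ---------------------------------------------------------------------------

_CH_GAINS = (0.85, 0.90, 1.00, 0.90, 0.85)
_CH_LOCK = (0.50, 0.70, 1.00, 0.70, 0.50)  # channel 3 locks strongest

_BURST_TIME_JITTER_FRAC = 0.45  # of one respiratory period, at zero coupling


def _burst_envelope(burst_times, amps, width_s, duration, fs):
    n = int(round(duration * fs))
    env = np.zeros(n)
    w = int(round(width_s * fs))
    burst = np.hanning(max(w, 3))
    half = len(burst) // 2
    idx0 = np.round(burst_times * fs).astype(int)
    for i0, a in zip(idx0, amps):
        lo, hi = i0 - half, i0 - half + len(burst)
        if hi <= 0 or lo >= n:
            continue
        wlo, whi = max(0, -lo), len(burst) - max(0, hi - n)
        env[max(0, lo):min(n, hi)] += a * burst[wlo:whi]
    return env


def generate_semg(spec: CohortSpec, group: str, respiratory_phase, rng,
                  return_components=False):
    """Generate the 5 sEMG channels (mV, 1 kHz) for one patient.

    Broadband 20-450 Hz bursts are placed at respiratory-phase peaks; at
    coupling < 1 burst times are jittered by a per-burst Gaussian offset
    whose scale grows as coupling decreases, so phase-locking (and hence
    coherence with the ECG-derived signals) degrades smoothly.  Channel 3
    retains the strongest locking.
    """
    gp = spec.group_params(group)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fs = spec.fs_emg
    n = int(round(spec.duration * fs))

    # phase-peak times: unwrapped phase crosses pi/2 + 2*pi*k
    pt, phi = respiratory_phase
    k0 = int(np.ceil((phi[0] - np.pi / 2) / (2 * np.pi)))
    k1 = int(np.floor((phi[-1] - np.pi / 2) / (2 * np.pi)))
    targets = np.pi / 2 + 2.0 * np.pi * np.arange(k0, k1 + 1)
    locked_times = np.interp(targets, phi, pt)
    period = 1.0 / gp.resp_rate_hz
    width = 0.4 * period

    sos_band = sps.butter(4, [20.0, 450.0], btype="bandpass", fs=fs,
                          output="sos")
    # slow broadband gain wander (0.2-1.5 Hz) built on a coarse grid; this
    # is what makes the burst envelope irregular (higher entropy) without
    # disturbing its respiratory phase-locking
    n_coarse = int(np.ceil(spec.duration * _PHASE_FS)) + 1
    t_coarse = np.arange(n_coarse) / _PHASE_FS
    sos_slow = sps.butter(2, [0.2, 1.5], btype="bandpass", fs=_PHASE_FS,
                          output="sos")
    clean = np.zeros((5, n))
    noise = np.empty_like(clean)
    t_hi = np.arange(n) / fs
    for ch in range(5):
        c_ch = gp.coupling * _CH_LOCK[ch]
        sigma_t = _BURST_TIME_JITTER_FRAC * period * (1.0 - c_ch)
        times = locked_times + sigma_t * rng.standard_normal(locked_times.size)
        amps = 1.0 + 0.3 * gp.emg_irregularity * rng.standard_normal(times.size)
        amps = np.maximum(amps, 0.15)
        env = _burst_envelope(times, amps, width, spec.duration, fs)
        wander = sps.sosfilt(sos_slow, rng.standard_normal(n_coarse))
        sd = wander.std()
        if sd > 0:
            wander /= sd
        gain = np.maximum(1.0 + 0.5 * gp.emg_irregularity * wander, 0.1)
        env *= np.interp(t_hi, t_coarse, gain)
        # fluctuating tonic (between-burst) activity: the carrier of the
        # success group's richer moment-to-moment variability
        tonic = sps.sosfilt(sos_slow, rng.standard_normal(n_coarse))
        sd = tonic.std()
        if sd > 0:
            tonic /= sd
        env += gp.emg_irregularity * np.abs(np.interp(t_hi, t_coarse, tonic))
        carrier = sps.sosfilt(sos_band, rng.standard_normal(n))
        carrier /= carrier.std()
        clean[ch] = gp.emg_amp_mv * _CH_GAINS[ch] * env * carrier
        w = rng.standard_normal(n)
        p_noise = np.var(clean[ch]) * 10.0 ** (-spec.snr_emg_db / 10.0)
        noise[ch] = w * np.sqrt(p_noise / np.var(w))
    out = clean + noise
    if return_components:
        return out, clean, noise
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_recording(spec: CohortSpec, group: str, patient_id: str,
                       seed) -> Recording:
    """One patient: shared respiratory phase feeds both modalities."""
    rng = np.random.default_rng(seed)
    gp = spec.group_params(group)
    phase = make_resp_phase(spec.duration, gp.resp_rate_hz,
                            spec.resp_jitter, rng)
    ecg = generate_ecg(spec, group, rng, phase=phase)
    semg = generate_semg(spec, group, phase, rng)
    return Recording(patient_id=patient_id, group=group, ecg=ecg, semg=semg,
                     fs_ecg=spec.fs_ecg, fs_emg=spec.fs_emg)


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate ``n_success + n_failure`` labelled recordings.

    Per-patient seeds are spawned deterministically from ``spec.seed``, so
    the cohort is bit-reproducible and any patient can be regenerated in
    isolation.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_success + spec.n_failure)
    recs = []
    for i in range(spec.n_success):
        recs.append(generate_recording(spec, "success", f"S{i + 1:02d}",
                                       children[i]))
    for j in range(spec.n_failure):
        recs.append(generate_recording(spec, "failure", f"F{j + 1:02d}",
                                       children[spec.n_success + j]))
    logger.info("generated cohort: %d success, %d failure, %.0f s each",
                spec.n_success, spec.n_failure, spec.duration)
    return recs
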