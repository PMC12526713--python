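# Methods

`emgwean` implements a complete analysis chain for classifying
mechanical-ventilation weaning outcome (success vs. failure) from
non-invasive recordings made during a spontaneous breathing trial: 3-lead
ECG sampled at 128 Hz and 5-channel diaphragm surface EMG sampled at
1 kHz.  Because clinical recordings of this kind are not freely
redistributable, the package ships a synthetic cohort generator whose
statistical structure matches what the analysis consumes; every stage is
tested end-to-end against it.

## Signal model and derived series

Preprocessing applies zero-phase second-order-section IIR filters: a
Q = 35 notch at the mains frequency (60 Hz) on both modalities, a 0.05 Hz
high-pass on the ECG, a 20 Hz high-pass on the sEMG, followed by linear
detrending.  Filter family and order (4th-order Butterworth) are our
choices; cutoffs are the standard clinical settings.  The sEMG is then
polyphase-resampled 1000 → 128 Hz (ratio 16/125) through a long
Kaiser-windowed FIR whose cutoff sits at 0.94 of the output Nyquist, so
tones just above 64 Hz are attenuated to ~1 % rather than the ~10 % the
default resampling filter leaves.  Despiking replaces samples whose
MAD-scale robust z-score exceeds a threshold by linear interpolation; in
the pipeline the threshold adapts to three times the channel's own 99.9th
percentile z-score, because impulsive physiology (QRS complexes, EMG
bursts) legitimately reaches z ≈ 100 on the MAD scale and must not be
treated as artifact.

Four analysis series are derived on one uniform grid at fa = 4 Hz:

* **EDR** (ECG-derived respiration): QRS peak-to-peak amplitudes measured
  in a ±60 ms window around each R peak, interpolated with shape-preserving
  PCHIP (no overshoot beyond the amplitude range).  R peaks come from a
  Pan–Tompkins-style detector (5–30 Hz band-pass, differentiate, square,
  0.15 s integration); the detection threshold is an Otsu split of the log
  candidate-peak heights, which tolerates deep respiratory amplitude
  modulation of the QRS.  Beats implying RR < 0.27 s or > 3 s are rejected.
* **HRV**: instantaneous rate 1/RR, with recursive outlier correction —
  while any sample deviates from the series mean by more than 18 % of the
  mean, the worst offender is replaced by cubic-spline interpolation from
  the currently conforming samples (clipped to their range so edge
  extrapolation cannot inject new outliers) and the mean is recomputed.
  The corrected series is spline-interpolated at 1 Hz and upsampled to fa.
  The 18 % criterion is applied against the global series mean.
* **EMGe**: cubic spline through the peaks of the rectified sEMG, followed
  by local quadratic least-squares smoothing over a 9 ms window (a no-op at
  128 Hz, where 9 ms is barely one sample; the window is configurable) and
  a zero-phase low-pass at 0.45·fa before sampling on the fa grid — the
  peak-spline envelope carries broadband carrier-induced jitter that would
  otherwise alias into the analysis band.
* **EMGi**: cubic spline through rectified-signal peaks above the 70th
  percentile with an enforced 0.15 s minimum separation (larger peak wins).

fa = 4 Hz is used for all four series (the respiratory HF band extends to
0.4 Hz; coherence between the series requires one common rate).  HRV is
built at 1 Hz first, honouring the cardiology convention, then upsampled.

The representative (sEMG channel, ECG lead) pair is the argmax of the
normalised cross-correlation between per-channel EMGe and per-lead EDR
over lags |τ| ≤ 5 s (one respiratory cycle), computed on z-scored series.
On default synthetic cohorts this selects channel 3 and lead II with
values above 0.4, matching the physiological expectation that the
xiphisternal channel best captures diaphragm activity.

## Time-varying parameterisation

A long outer window (300 s, 50 % overlap) slides over the derived series;
each outer window contributes one value per parameter, so a 3600-s series
yields exactly 23 windows.  Within an outer window:

* per-signal spectra use a single Hann-tapered, mean-removed modified
  periodogram of the whole window (frequency resolution 1/300 Hz);
* coherence uses Welch/MSC with 60-s sub-segments at 50 % overlap
  (9 averages), because an MSC estimate from one segment is identically 1.

Band descriptors per band (LF 0.04–0.15 Hz, HF 0.15–0.4 Hz; closed
intervals, ties toward the lowest frequency): peak power Hp, its frequency
Fp, trapezoidal band power P, and the slopes Us = (Hp − S(f_lo))/(Fp − f_lo)
and Ds = (S(f_hi) − Hp)/(f_hi − Fp); when the peak falls on a band edge the
corresponding slope is zero and flagged.  Coherence K(f) =
|Sxy|²/(Sxx·Syy) is parameterised the same way on the HF band, plus the
in-band RMS and nearest-bin values at 0.02 and 0.04 Hz looked up on the
full-range coherence grid.  The canonical pairs are EMGe–EDR, EMGe–HRV,
EMGi–EDR and EMGi–HRV; the EMGi–EMGe pair is supported behind a flag but
excluded from the canonical catalog so the feature count stays exact.

Approximate and sample entropy use Chebyshev template matching with m = 2
and r = 0.15 times the sample SD of each window (per-window r, consistent
with the time-varying setting).  ApEn includes self-matches (always
finite); SampEn excludes them and is reported as NaN when no template pair
matches, such windows being dropped from the summaries with a logged
count.  Both are validated to 1e-12 against an independent brute-force
double-loop implementation.

## Features, selection, classification

Each of the 80 base parameters (40 spectral + 32 coherence + 8 entropy) is
summarised over its windows by mean, coefficient of variation s/x̄,
kurtosis Σ(x−x̄)⁴/(n·s⁴) (sample SD, n−1) and IQR with type-7 linear
quantiles — 320 features per patient.  Selection is two-stage: a
two-sided Mann–Whitney U test per feature at raw α = 0.05 (no
multiple-testing correction — appropriate for small exploratory cohorts
and deliberately matching common practice in this literature), then a
greedy Spearman de-correlation: while any pair of survivors has
|ρ| ≥ 0.6, the member with the larger mean |ρ| to all others is dropped
(ties to the larger U-test p-value).  The U test was chosen over Welch's
t because small-n physiological features are rarely normal; Welch's t is
available by configuration.

Classifiers: Gaussian Naive Bayes on raw features; KNN (k = 5 default,
Spearman distance implemented as correlation distance on rank-transformed
feature vectors, nine other metrics available) and a polynomial-kernel
SVM (degree 5, C = 1) on features z-scored with training-fold statistics.
Weaning success is the positive class, which fixes the
sensitivity/specificity semantics.  Evaluation repeats stratified random
70/30 splits (1000 runs by default), reporting mean ± SD of accuracy,
specificity, sensitivity and F-score and the run-summed confusion matrix;
splits whose test fold lacks a class are redrawn and counted.  Sequential
backward elimination scores the removal of every remaining feature with a
reduced-run evaluation (100 runs), removes the least impactful one, and
returns the subset with the global best mean accuracy (never worse than
the full set by construction).  KNN exact-tie votes follow scikit-learn's
neighbor-order rule rather than a smaller-distance-sum rule; with odd k
and continuous features exact ties are measure-zero.

## Synthetic cohort generator

The generator emulates only what the analysis consumes, not ECG/EMG
morphology: QRS complexes are Mexican-hat wavelets (σ = 20 ms, so the
complex is well sampled at 128 Hz and its spectral peak ≈ 11 Hz sits inside
the QRS detection band); EMG bursts are 20–450 Hz band-limited noise under
a Hann envelope locked to a shared respiratory phase.  The phase has
slowly drifting frequency (3 % relative jitter); RR intervals carry an LF
sinusoid (0.10 Hz, 5 %), respiratory sinus arrhythmia (4 %) and white
jitter (1 %).  Per-patient seeds are spawned from the cohort seed with
`numpy.random.SeedSequence`, so any patient is reproducible in isolation.

Group contrasts (defaults chosen once from the reported physiology of
weaning outcome and from typical trial demographics):

| parameter | success | failure | drives |
|---|---|---|---|
| respiratory rate | 0.31 Hz (18.6/min) | 0.35 Hz (21/min) | Fp of HF band, HRV HF peak |
| QRS amplitude modulation depth | 0.45 | 0.15 | EDR band power/peak |
| EMG burst amplitude | 0.015 mV | 0.035 mV | EMG envelope power |
| burst irregularity | 0.50 | 0.20 | EMG entropies |
| respiratory coupling | 0.90 | 0.50 | EMGe/EMGi coherences |

Burst irregularity acts through two mechanisms: a slow broadband
(0.2–1.5 Hz) gain wander on the burst train and a fluctuating tonic
(between-burst) activity floor.  The tonic component is what makes the
success group's envelope genuinely less predictable at every instant —
per-burst amplitude jitter alone is largely invisible to sample entropy at
a 4 Hz envelope rate, while the failure group's weaker phase-locking
otherwise *adds* entropy and would invert the intended contrast.  Channel
gains fix channel 3 as the strongest-locked channel (1.0 vs 0.7/0.5
locking for its neighbours), and ECG lead II carries the deepest EDR
modulation.  Additive noise is scaled per channel to 21 dB (ECG) and
14 dB (EMG) clean-to-noise power ratio.

What the generator does not emulate: P/T waves, ectopy, motion artifacts,
electrode contact changes, ECG cross-talk into the sEMG, or non-stationary
clinical deterioration.  Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it is designed to measure,
not that it is robust to every artifact of bedside recordings.

## SNR accounting

`compute_snr` estimates SNR as the power ratio of a Savitzky–Golay
least-squares baseline (order 3, 0.5 s window) to its residual.  This is
consistent only when the clean component lies inside the baseline passband
(≈ 2 Hz at 128 Hz input): it recovers a constructed sine + noise mixture
to within 1 dB and rates the derived respiration-scale series (EDR ≈ 45 dB,
smoothed EMGe ≈ 30 dB on default cohorts, both far above the 10 dB floor
commonly quoted for usable surface EMG).  Applied to raw broadband EMG or
impulsive QRS trains it counts fast signal content as noise and is only a
conservative quality floor; the generator's noise targeting is therefore
verified against its own clean/noise decomposition (±2 dB), not through
this estimator.

## Problem sizes

Defaults mirror a realistic study: 19 success + 21 failure patients,
60-minute recordings, 1000 evaluation runs.  The test-suite and the
acceptance script run scaled-down versions chosen so every stage still has
its minimum structure: 600-s recordings (two overlapping outer windows —
the shortest recording the time-varying layer accepts) for the 20-seed
contrast-recovery checks, 900-s recordings (three windows) and the full
19/21 cohort for the acceptance script, and 200–500 evaluation runs.
Window counts that small make the CV/kurtosis/IQR summaries crude; the
designed contrasts are carried by the mean statistics, which is also what
the recovery checks assert.

## Known limitations

* ECG artifact contamination of the diaphragm sEMG is not removed before
  envelope extraction (no gating or template subtraction); the synthetic
  data contains no such cross-talk either.
* The recursive HRV outlier rule is interpreted against the global series
  mean; running-mean readings would differ on drifting records.
* EDF support covers the plain 16-bit continuous-recording profile (1-s
  records, integer sampling rates); EDF+ annotations and free-form
  metadata beyond patient id and group label do not survive a round-trip.
* With only two 300-s windows per 600-s test recording, windowed kurtosis
  is degenerate (identically 1 for non-constant pairs); it becomes
  informative only at realistic recording lengths.
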