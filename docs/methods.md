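# Methods

This note documents the models, numerical choices, and design decisions
behind `mecg`, and what the synthetic tests do and do not demonstrate.

## Signal model and pipeline assumptions

The package assumes the cardiac field reaches many MEG sensors (and the
reference sensors) approximately linearly and instantaneously, so that a
single cardiac time course can be recovered either by linear unmixing
(FastICA) or by picking one strongly coupled reference sensor. It targets
sinus rhythm at rest: the 0.5 s minimum inter-peak distance caps detectable
rates at 120 bpm, and no ectopic-beat classification or arrhythmia handling
is attempted.

Processing order is: resample → bandpass → source extraction → baseline
correction/normalization → wavelet denoise → peak detection → RR
computation → outlier correction → HRV metrics/spectra. Resampling precedes
filtering so all recordings share one analysis rate.

## Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `resample_rate` | 600 | Hz | common analysis rate; R-peak timing then has 1.7 ms resolution |
| `band_low`, `band_high` | 0.5, 45 | Hz | retains P-QRS-T morphology, rejects drift and line noise |
| `ica_n_components` | 15 | — | sufficient to isolate one cardiac component from 27 temporal channels |
| `ica_seed` | 0 | — | fixed for reproducibility; recorded in every output |
| `min_distance_s` | 0.5 | s | physiological refractory spacing (≤ 120 bpm) |
| `n_amp` | 2 | — | amplitude-gate width in candidate SDs |
| `n_rr` | 1.5 | — | RR outlier band in interval SDs |
| `tachogram_points` | 850 | — | even resampling length; ≈ 2.4 Hz over 5–6 min |
| misalignment threshold | 0.02 | s | offset above which a peak pair counts as misaligned |
| quality gate | < 3% misaligned and ≥ 98% beat agreement | — | recordings failing either are unusable for HRV |
| benchmark tolerance | ±0.05 | s | TP window for sensitivity/PPV/F1 |
| CCC window | 30 | intervals | short-window paired agreement; SDNN deliberately excluded (unreliable at n = 30) |

All statistics in this package use the population (1/N) standard deviation
— including SDNN, the amplitude/RR gates, and Bland–Altman — because the
gate formulas are defined with 1/N normalization and mixing conventions
within one pipeline invites subtle disagreements. Many HRV tools use
1/(N−1); differences are negligible at N > 100 but visible in short
windows.

## Numerical choices

- **FIR filtering** delegates to MNE-Python's `filter_data` (zero-phase,
  Hamming window, `firwin` design; transition bandwidths
  `min(max(f·0.25, 2 Hz), f)` at each edge). Zero phase matters: any group
  delay would bias every R-peak time.
- **Normalization** is mean subtraction followed by division by the maximum
  absolute value, putting R-peaks near ±1 so amplitude thresholds are
  scale-free. Constant signals are rejected rather than normalized.
- **Wavelet denoising** keeps only the level-3 approximation (A3) of a
  symlet-4 DWT with symmetric boundary extension, zeroing D1–D3. At 600 Hz
  this retains ~0–37 Hz, preserving QRS energy while stripping
  high-frequency noise. Reconstruction length is truncated to the input
  length.
- **Polarity**: ICA component sign is arbitrary, so detection negates the
  trace when |min| > |max| and records the flip. Detection of a trace and
  its negation therefore yields identical peaks.
- **Tie-breaks**: spacing conflicts between equal-amplitude candidates keep
  the earlier sample; plateau maxima report their first sample. Both rules
  exist purely for determinism.
- **Amplitude statistics** are computed on the spacing-enforced candidate
  set and applied in a single pass (no re-estimation after removal).
- **RR correction** interpolates RR against the pre-correction cumulative
  time x; a run of consecutive flags receives one linear segment, and
  flagged boundary intervals take the nearest valid value (constant
  extension). Flag statistics are computed once; correction is never
  iterated. The interval count never changes.
- **Tachogram**: natural cubic spline (zero second derivative at the ends)
  through (x_i, RR_i), evaluated at 850 evenly spaced points on
  [x_1, x_last]. The reported rate is (n_points − 1)/span — about 2.4 Hz
  for 5–6 min recordings — rather than a hard-coded constant.
- **Welch PSD**: Hamming window, 256-point segments, constant detrend, no
  overlap; band powers by trapezoid on the Welch grid. VLF
  (0.0033–0.04 Hz) is always reported but flagged non-interpretable unless
  the span covers ≥ 10 cycles of the lowest VLF frequency (~50 min), so it
  is never interpretable on 5–6 min recordings.
- **CWT**: analytic Morlet with centre frequency 6 rad/s (PyWavelets
  `cmor1.0-0.954930`), 64 log-spaced scales over 0.5–45 Hz.
- **DTW** uses squared local costs accumulated over an unconstrained
  warping path, returning the square root of the optimal accumulated cost
  (the convention of the DTAIDistance library). An exhaustive-path oracle
  in the test suite verifies the dynamic program exactly for short series.
- **Peak pairing** operationalizes "nearest in sequence" as
  order-preserving greedy matching: each M-ECG peak takes its nearest
  I-ECG peak at or after the previously consumed one, each reference peak
  used at most once, equidistant ties to the earlier peak. A consequence —
  visible in the tests and faithful to the metric — is that one missing
  reference beat misaligns the whole tail of a recording; this is what
  makes the gate a stringent quality criterion. Beat-count agreement is
  100·min(counts)/max(counts).
- **Mann–Whitney U** on PSDs compares the value vectors over the common
  frequency grid. Lin's CCC uses population moments per window set.
  Element-wise statistics truncate to the common length; DTW is the
  designated length-tolerant comparison.

## The synthetic generator

`SyntheticSpec` defaults define the study conditions: 300 s recordings,
mean RR 0.8 s (75 bpm), LF modulation 0.1 Hz / 0.03 s, HF modulation
0.25 Hz / 0.02 s, beat-timing jitter 0.005 s, QRS width 0.08 s with a
smaller T wave, 27 MEG-like channels with mixing weights ~ U(0.5, 1.5) and
channel noise SD 0.07 (≈ 10 dB SNR at unit weight), one strongly coupled
reference sensor plus one noise-only reference, and a clean ECG channel.

The beat model is sinusoid-plus-jitter, not integral pulse frequency
modulation: each interval is mean RR plus LF and HF sinusoids (evaluated at
the accumulated beat time, so the series is self-consistent) plus Gaussian
jitter. This keeps closed-form expectations — a pure modulation of
amplitude a has RR standard deviation a/√2 and a known spectral line — at
the cost of physiological fidelity in the fine structure.

Two generator choices deserve emphasis because they were *forced* by
degeneracies of over-idealized synthesis, and both model documented
physiology:

- **R-amplitude modulation** (`r_amp_mod` = 0.1, sinusoidal at the HF /
  respiratory frequency, sharing the respiratory phase). A
  constant-amplitude bump train leaves the candidate-amplitude spread equal
  to the sensor noise — a tight Gaussian — and a ±2σ gate then trims ~4.6%
  of perfectly good beats *by construction*, which no real recording
  exhibits: real R-peak amplitude varies by ~10% with respiration (the
  basis of ECG-derived respiration). With the bounded modulation dominating
  the spread, the ±2σ band contains essentially all true beats, and the
  gate does what it is designed to do: remove gross artifacts.
- **Random LF/HF modulation phases** per seed (recorded in `GroundTruth`).
  Respiration and baroreflex phase are arbitrary at recording onset; with
  fixed phases, two "independent" realizations share their entire
  deterministic structure and differ only in 5 ms jitter.

What the generator does **not** emulate: realistic MEG forward fields
(mixing is a scalar weight per channel), respiration-coupled noise,
baseline wander, electrode/sensor artifacts, ectopy, or non-stationary
heart rate. Passing tests therefore show that the algorithms are correct
and well-calibrated under linear mixing and stationary sinus rhythm — not
that the pipeline is robust to every pathology of real MEG data (the
quality gate exists precisely because real recordings sometimes are not
usable).

## Statistical calibration of the Mann–Whitney check

Rank-test calibration presupposes exchangeable samples. Two
modulation-dominated RR series — even with independent random phases — are
each a balanced, systematic sweep of the same underlying waveform, so
their rank sums nearly coincide and the test is far *below* its nominal
level (p-values pile up near 1; the same conservatism is visible when the
test is applied to real tachograms). The calibration test therefore uses
the generator's jitter-dominated configuration (no deterministic
modulation, jitter SD 0.03 s, matching a typical resting SDNN of ~0.03 s),
where beats are iid and the 5% level is meaningful; a companion test
asserts that the modulated configuration errs on the conservative side
only. Measured type-I rate over 200 replicates: ~0.04.

## Problem sizes

Default test and acceptance problem sizes are the study conditions
themselves: 5-minute recordings (~375 beats) for pipeline-level checks,
with 1–2 minute recordings for unit-level fixtures, 10 mixture seeds of
2 minutes each for the ICA-recovery check, and 200 replicate pairs for the
type-I calibration. These sizes give the checks their statistical meaning
(e.g. ±2.5% tolerance on a 5% rejection rate needs ≥ 200 replicates)
while remaining desk-scale.

## Known limitations

- The reference-sensor route presumes at least one reference channel with
  strong cardiac coupling; the generator guarantees one, real systems may
  not.
- The advisory component ranking can prefer a strongly periodic
  non-cardiac source (e.g. an undamped mechanical oscillation inside the
  beat band) over a heavily jittered cardiac component; the final choice
  is deliberately a user parameter, not an oracle.
- DTW distances depend on series length; they are comparable between
  routes on the same recording, not across recordings of different
  duration.
- FIF/CTF reading delegates to MNE-Python; channel roles map from MNE
  channel types (`mag`/`grad` → gradiometer, `ref_meg` → reference,
  `ecg` → ECG), and anything else becomes `other`. The CTF reader is
  exercised only through MNE's own machinery.
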