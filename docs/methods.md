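# Methods

This note documents the models, parameter choices and numerical
conventions behind `neurovitals`, and what the synthetic-data tests do
and do not establish about real recordings.

## Stimulus model

A run is `n_cycles` (default 60) cycles of `cycle_duration` (default
5 s). Each cycle presents a prime word at its start, the target word
800 ms later (600 ms word + 200 ms gap), then `tones_per_cycle`
(default 4) tones of 100 ms spread evenly over the remaining cycle time.
Tone count per cycle and word duration are design choices — they fill a
5 s cycle with one pair plus four tones, close to the maximum trial rate
for the two interleaved paradigms. Deviant tones are exactly
`round(n_tones × 0.20)` and incongruent pairs exactly
`round(n_pairs × 0.50)`, placed by sampling without replacement with the
constraint that the sequence's first tone is standard (deviance is
undefined before a standard has been established — common oddball
practice). Every onset receives independent uniform ±50 ms jitter to
decorrelate stimulation from ongoing ~10 Hz alpha; the distribution and
width are this package's choice. Stimulus intensities (75/100 dB) are
carried as metadata only; no audio is synthesized. Sample indices use
round-half-away-from-zero.

## Synthetic EEG

Components are Gaussian-windowed bumps `A·exp(−((t−L)/w)²/2)`, truncated
to zero beyond ±3w (widths w: N100 15 ms, P300 40 ms, N400 50 ms —
early components are sharper). Scalp topography is a fixed gain per
channel with unit gain at the measurement channel (N100 at Cz, P300/N400
at Pz), so the injected amplitude is what that channel sees. The
differential-response model keeps condition contrasts in the raw
single-condition averages (no subtraction is used downstream): deviant
tones evoke N100 + P300; standard tones an attenuated N100 (50%);
incongruent targets a full N400; congruent targets a reduced N400 (30%);
primes nothing.

Group presets carry the published young/older group means and SDs
(young P300 11.09 ± 3.39 μV at 276.00 ± 20.59 ms; older 10.36 ± 1.91 μV
at 310.00 ± 15.02 ms; young N400 −5.93 ± 3.60 μV at 460.67 ± 65.11 ms;
older −4.51 ± 1.00 μV at 516.67 ± 57.53 ms; N100 −6.74 ± 2.13 μV at
100 ms for both). The N100 latency SD is not published and is fixed at
10 ms. The table prints N400 amplitudes as magnitudes; the simulator
stores both N100 and N400 as negative-signed values, which is the
convention the scoring brackets require. Preset SDs act **between**
participants; trial-to-trial scatter is separate and fixed at 30% of the
mean magnitude (amplitude) and 8 ms (latency) — typical single-trial ERP
variability. Drawn amplitudes keep their component's sign (magnitude
floored at 0.5 μV) and drawn latencies are clamped inside the detection
window with a margin, so every simulated participant has a measurable
response; the clamp is a simulation-measurability device and slightly
truncates wide latency distributions (relevant when using draws to
study group effect sizes — see the group-comparison section).

Noise: 1/f-shaped background (flat below 1 Hz) at 5 μV RMS per channel,
10 Hz alpha at 2 μV on scalp channels with random phase, common-mode
60 Hz line at 2 μV, and blinks as 400 ms raised-cosine deflections of
150 μV on the vertical EOG at 10/min, propagated to the scalp with a
frontal gradient (Fz 0.4, Cz 0.2, Pz 0.1). All randomness flows through
one seeded generator; seeds are logged in recording metadata.

What the simulator does **not** emulate: volume conduction/forward
modelling, word acoustics, non-stationary noise, muscle or movement
artifacts, electrode drift or impedance changes, or inter-individual
topography differences. Tests passing on this generator therefore
establish correctness of the signal-processing and scoring chain under
a plausible ERP signal model — not field performance on human data.

## Preprocessing

4th-order Butterworth 1–20 Hz bandpass plus 2nd-order IIR notch at
60 Hz (Q = 30), both applied forward–backward (`sosfiltfilt`/
`filtfilt`): zero phase, so component latencies are preserved (verified
to within one sample). The corner frequencies are the published
protocol; the realization (order, topology) is this package's choice.
The 1 Hz high-pass necessarily trims some absolute peak amplitude from
slow components (~13% for a 40 ms-wide P300 bump); the peak-to-peak
measure is much less affected because both extrema shift together.

Ocular correction regresses each scalp channel on the EOG channels by
least squares (no intercept; the data are already high-passed and
zero-mean) and keeps the residual. Epochs are −100..900 ms (501 samples
at 500 Hz, closed at both ends, 0-based indexing); baseline is the
half-open [−100, 0) ms. Word-pair epochs lock to the **target** word —
the semantic violation is realized at the second word. Artifact
rejection marks epochs with any scalp sample beyond ±100 μV; the
published pipeline's "pattern recognition de-noising" is unspecified, so
this standard deterministic amplitude criterion stands in its place.

## Component detection

A component is the most extreme correctly-signed sample inside its
window at its channel — N100: 70–170 ms at Cz; P300: 250–500 ms at Pz;
N400: 300–700 ms at Pz. Windows span the published group means ±3
between-participant SDs; channels follow classic midline maxima (the
recording montage is Fz/Cz/Pz but no site assignment is published).
Amplitude is peak-to-peak against the preceding opposite-polarity
extremum, searched backward to 50 ms (N100) or to the previous
component's window start (P300: 70 ms, N400: 250 ms). With no preceding
opposite deflection the measure falls back to the 0 μV baseline and is
flagged. Ties break to the earliest sample. Scoring uses averages pooled
over a participant's (typically 3) runs; classification uses single-run
averages.

## Classification

Feature vectors concatenate the three scalp channels' trial-averaged
epochs, decimated by 5 (3 × 101 = 303 features). Folds are assigned by
run, which simultaneously stratifies (each run contributes one
observation per class) and prevents twin leakage (a run's two averages
share residual noise). Standardization is fit on training folds only.
The SVM is RBF with `gamma = 'scale'` and C = 1 (only the kernel is
prescribed; no grid search). The permutation test shuffles labels within
each fold's training set, retrains, and evaluates against the true test
labels; `p = (1 + #{null ≥ observed}) / (n_perm + 1)` — the +1 Monte
Carlo correction avoids p = 0. Standardization parameters are
label-independent, so they are precomputed per fold and shared across
permutations (an optimization, not a change of procedure).

## Normative database and scoring

Quartiles use linear interpolation between order statistics; fencing
removes values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] in a single pass
(no re-fencing), independently per measure. Statistics (μ, σ, min, max,
best) come from kept values only. Bracket scoring operates on signed
amplitudes, which makes the mirrored inequalities for negative
components coherent with "most negative is best". At exact bracket
boundaries the value takes the lower score (the 5-point branch is a
strict inequality). EBS is clamped to [0, 1] for values outside the
normative span. Components are weighted equally; A/B/C sub-scores sum
amplitude and latency points.

Group comparisons: from raw samples, a Shapiro–Wilk gate (α = 0.05 per
sample) selects a two-tailed independent t-test or the Wilcoxon
rank-sum; from printed summaries, the pooled-variance t with
df = n1+n2−2. The published N400-latency p = 0.07 is not recoverable
from the printed summary statistics under a two-tailed pooled t-test
(closed form gives p ≈ 0.145); it is reported as computed, not matched.

## Calibration QC

The test signal is an equal-amplitude sum of 5/10/15/30 Hz sinusoids.
SNR integrates Welch power (4 s Hann segments, 0.25 Hz resolution) over
±0.5 Hz around each signal tone, divided by the same band around 60 Hz;
the integration band and segment length are this package's choices. With
essentially zero 60 Hz power the ratio is capped at 10¹². Note the
white-noise floor of this statistic is 4 (four signal bands vs one noise
band), not 0. Day-over-day stability is the mean absolute percentage
change of session peak-to-peak voltage between consecutive sessions.

## Problem sizes and test design

The test suite runs entirely on generated data. Cohort-level checks use
6 participants × 3 runs per group (the validation-study sample size);
the group-difference power check draws P300 latencies from the preset
distributions directly (the detection-window clamp would truncate the
young tail and shrink the 34 ms effect) and uses 2000 replicate cohort
draws so that Monte-Carlo error (SD ≈ 0.8 percentage points) is small
against the 80% detection threshold — the exact noncentral-t power at
this effect size is 0.837. Permutation-calibration checks use 99–1000
permutations and 50 replicate datasets with 5-fold CV on 40
observations, sized to keep the suite fast while leaving the
Kolmogorov–Smirnov uniformity test sensitive.

## Known limitations

* Published human-data quantities that depend on the original N = 100
  normative cohort and the 12-participant validation recordings (SVM
  accuracies of 98.96%/86.81%, per-measure outlier removal counts, the
  1.45% hardware drift figure) cannot be reproduced from synthetic data
  and are not targets; the suite substitutes property-based checks.
* The EDF writer path is absent: recordings are written as CSV + JSON
  sidecar; EDF is supported on input (via the optional mne dependency).
* Single-pass fencing assumes per-measure independence; participants
  are not removed jointly across measures.
* The peak-to-peak amplitude depends on the preceding-extremum search
  bound; components riding on overlapping deflections (e.g., P300 after
  a large N100) measure systematically larger than their injected peak
  values. This is inherent to the measure, not an error.
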