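# Methods

This note documents the models, parameters, and numerical choices behind
`phonemebci`, and what the synthetic benchmark does and does not show.

## Data model and file conventions

A trial is one imagined-speech attempt: 16 channels (10–20 labels Fp1, Fp2,
F7, F3, F4, F8, T3, C3, C4, T4, T5, T6, P3, P4, O1, O2 — fixed order, since
feature positions depend on it) at 250 Hz for nominally 500 samples (2 s);
lengths in [450, 550] are accepted, others rejected at load. Trials are
stored one CSV per trial, `P{participant:02d}_S{session}_PH{phoneme:02d}_T{trial}.csv`,
header = channel labels, one row per sample, microvolts, written with 17
significant digits so a write→read round trip is bit-exact. A `.failed`
sidecar marks a failed acquisition timestamp. Retention rules: trials
without a valid timestamp are excluded, and a participant is dropped
entirely unless every one of the 44 phonemes has at least two retained
trials. The packaged phoneme inventory is the conventional 44-phoneme
English set (24 consonants, 12 monophthongs, 8 diphthongs) with
ARPAbet-style symbols; any fixed 44-symbol inventory is interchangeable
for classification.

## Preprocessing

Order of operations is fixed: split → baseline → reject → filter.
Rejection deliberately uses *unfiltered* amplitudes so that broadband
transients are judged at full size.

- **Windows.** Two consecutive, non-overlapping 1 s windows (samples
  0–249, 250–499); excess samples are discarded; shorter trials are marked
  rejected ("short").
- **Amplitude statistic.** Mean absolute amplitude over channels and
  samples of a window. The session baseline is the mean and SD (population,
  ddof=0) of this statistic over all windows of the session, computed
  before any rejection (no iterative re-estimation). A trial is rejected
  ("artifact") when either window's statistic falls outside mean ± 3 SD
  (two-sided). The nominal false-positive rate of the rule (~0.3% of
  windows) is accepted.
- **Filtering.** 4th-order Butterworth band-pass with corners 0.1 Hz and
  123.75 Hz (the upper corner is clipped below the 125 Hz Nyquist, where
  the stated corner is unrealizable), then a 60 Hz notch of quality factor
  30, both zero-phase. On 250-sample windows the 0.1 Hz corner's and the
  notch's impulse responses are longer than the window, so forward–backward
  time-domain filtering is dominated by edge transients; the package
  therefore applies the identical zero-phase response |H(f)|² of the
  designed filters multiplicatively on the window's rFFT. This is exact for
  the filters' magnitude response, exactly linear, suppresses DC and a
  60.0 Hz tone to numerical zero, and leaves a 10 Hz tone within 0.01% of
  unit gain. The trade-off is circular (rather than linear) convolution,
  which is immaterial for the spectral and amplitude summaries extracted
  downstream.

## Feature inventory

35 features per channel window, in fixed order: temporal mean; 99.95th
percentile of |amplitude|; RMS; peak-to-peak; total 1–100 Hz power; the 5
band powers δ(1–4), θ(5–8), α(8–12), β(13–30), γ(30–100 Hz); the 10
half-band powers (each band split at its arithmetic midpoint, so α-low is
8–10 Hz); and the 15 corresponding relative powers (divided by total
1–100 Hz power, with 0/0 defined as 0). The percentile reading of "percent
intensity at 99.95%" and the completion of the enumerated spectral features
with total power, RMS, and peak-to-peak to reach exactly 35 are declared
conventions of this implementation.

Spectra use Welch's method with 125-sample Hann segments and 50% overlap
(2 segments per 1 s window, 2 Hz resolution — the finest that still
averages at least two segments). Band power integrates the density over
bins whose centers fall in [lo, hi) by the rectangle rule (Σ density × Δf),
which is well defined for single-bin bands and makes disjoint tilings
exactly additive. Consequences worth knowing at 2 Hz resolution: δ-high
(2.5–4 Hz) and θ-high (6.5–8 Hz) contain no bin centers and are constantly
0 (they score 0 in selection and are inert); bins at 4 and 12 Hz fall in
the 4–5 and 12–13 Hz gaps between canonical bands, so for an exact-bin
10 Hz tone the Hann leakage (¼ : 1 : ¼ over 8/10/12 Hz) puts exactly 5/6 of
the power in α rather than 1.

Vector assembly is window-major, then channel in montage order, then
inventory order: 35 × 16 = 560 per window, 1,120 per trial; one simulated
participant yields a 660 × 1,120 matrix (minus artifact rejections).

## ADEN feature selection

For one binary (event vs non-event) problem, each feature column is
z-scored over the training rows (population SD; zero-variance columns
score 0), and the score is |m₁ − m₀| / s_pooled of the z-scored column —
the magnitude of Cohen's *d* with the pooled within-class SD (ddof=1 per
class). The z-transform makes scores invariant to affine rescaling of any
column. Degenerate separations (zero pooled SD, nonzero distance) are
capped at 10⁶ to keep the ranking totally ordered. Top-k selection takes
the k ∈ [3, 6] largest scores, ties broken by lower column index (stable
sort); the default k = 6 uses the largest allowed set, since at these
dimensionalities more features cannot reduce the information available to
the classifier. Scores are computed from training rows only — the
interface never sees validation rows.

## Cross-validated one-vs-rest evaluation

Rows are assigned to 4 near-equal blocks, stratified by phoneme: per class
the shuffled rows are dealt round-robin with the starting block rotated by
class rank, so block totals stay near-equal (660 balanced rows → 165 per
block, 3–4 trials per phoneme per block). Each block validates once
(4-fold rotation). Per (phoneme, fold): the training rows are balanced by
undersampling non-events to the event count (events all kept); ADEN is
fitted on the balanced training rows; both splits are restricted to the
selected features; a classifier is fitted (behind a standardization step
fitted on the same rows) and scored on the untouched validation block at
its natural ~1:43 imbalance. Balanced-training/natural-validation is the
configuration under which a high accuracy can coexist with a moderate F1.
Folds whose training block contains a single class are skipped with a
warning; validation folds with a single class record a missing AUC,
excluded from aggregates.

Classifier defaults (all configurable): KNN k=5, uniform votes, score =
event-neighbor fraction; linear-kernel SVM, C=1, score = signed margin;
LDA with lsqr solver and automatic (Ledoit–Wolf) shrinkage, score =
discriminant value. A single run seed fans out deterministically to the
CV plan and to per-(phoneme, fold) balancing seeds via `SeedSequence`
spawn keys.

Intrasubject mode evaluates one participant's matrix; intersubject mode
pools all participants' rows into one matrix under the same CV scheme.

## Information transfer rate and the global feature ranking

ITR uses the Wolpaw form log₂N + P·log₂P + (1−P)·log₂((1−P)/(N−1))
bits/trial (limits 0·log₂0 ≡ 0), converted to bits/min by 60/trial-seconds.
It equals the mutual information of the symmetric confusion channel under
a uniform prior; the package carries an independent brute-force
mutual-information implementation used as a cross-check. At N=44 the
formula is 0 at P=1/44 and log₂44 ≈ 5.459 at P=1; at P=0.97 it gives
5.102 bits/trial (306.1 bits/min at 1 s trials) — reported figures of
5.07/304.15 for that operating point correspond to a slightly lower
unrounded accuracy.

The global feature ranking averages the full ADEN score vectors over all
one-vs-rest problems and folds of a run, collapses the two windows by
averaging, and sorts the 16 × 35 = 560 (feature, channel) pairs by
descending mean score; a top-125 view is exported.

## Synthetic EEG generator

The generator emulates the study conditions so every downstream stage is
testable without recordings: per participant, 3 sessions × 44 phonemes × 5
trials (660 trials), 500 samples at 250 Hz, written as the same CSV files
the loader reads. Generation is a pure function of the seed (per-trial
`SeedSequence` spawn keys), so identical seeds give byte-identical files.

Each trial is the sum of:

- **Background:** per-channel independent 1/f^β Gaussian noise (β = 1,
  RMS 10 µV — typical scalp-EEG amplitude), synthesized by FFT spectral
  shaping. No volume-conduction correlation between channels is modeled.
- **Mains:** a 60.0 Hz sinusoid, amplitude 2 µV, common phase across
  channels within a trial.
- **Class signature:** every phoneme receives the same total trial-average
  tone power, (effect_size × background RMS)²/2, concentrated on a seeded
  ordered pair of distinct slots among the 8 combinations of
  (window 1|2) × (F3|F7) × (low-γ 30–65 | high-γ 65–100 Hz), with a graded
  primary share in {0.55, 0.625, 0.70, 0.775, 0.85} and the remainder on
  the secondary slot; tone frequencies are seeded per class, kept clear of
  the sub-band edges so Hann leakage stays in-band. Sparse slot ownership
  gives every class a strongly mean-shifted marginal feature — the
  structure a univariate standardized-mean-difference ranking such as ADEN
  is built to recover; equalizing total power keeps gross amplitude
  uninformative, so separability lives in the gamma sub-band structure on
  the left-frontal channels. `effect_size = 0` zeroes every tone, making
  the classes exactly exchangeable (a proper null). Ground truth is
  exposed via `class_signatures()` for tests.
- **Artifacts:** with probability `artifact_rate` per trial, a 0.2 s
  raised-cosine transient, peak 6 × background RMS, applied across all 16
  channels (a movement-like event) at a random position — large enough to
  trigger the 3-SD rejection rule reliably.

What the synthetic benchmark does **not** emulate: volume conduction and
inter-channel correlation, non-stationary background spectra, ocular/EMG
artifact taxonomies, phase-locked or event-related dynamics, and any
realistic phoneme-specific cortical source geometry. Passing tests on this
benchmark therefore demonstrate that the pipeline recovers band-power
structure it is pointed at, with calibrated behavior under the null — not
that imagined phonemes are decodable from real EEG at these levels.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 660-trial,
1,120-feature pipeline (the study's own per-participant size) for the
calibration and recovery checks, and smaller 1-session configurations for
orchestration tests. Null calibration uses mean AUC over the 176
(phoneme × fold) cells, whose Monte-Carlo SD is ≈ 0.011, comfortably inside
the [0.45, 0.55] acceptance band. Zero-variance columns, empty bands,
degenerate separations, and single-class folds all have defined, logged
behavior rather than NaNs. Known limitations: the 2 Hz Welch resolution
zeroes two half-bands (above); the frequency-domain zero-phase filter is
circular; the balanced-undersampling step discards most non-event training
rows, which is faithful to the evaluated design but statistically
inefficient.
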