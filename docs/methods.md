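# Methods

This note documents the models and procedures implemented in `msgait`, the
parameter choices that matter, and what the synthetic experiments do and do
not establish about real sensor data.

## Synthetic signal model

All generated signals are tri-axial acceleration in g with axis order
[vertical, medial-lateral (ML), anterior-posterior (AP)] and gravity as a
constant +1 g on the vertical channel. The free-living sampling rate is
31.25 Hz; the lab hallway walk is generated at 250 Hz and resampled to
31.25 Hz before feature extraction so home and lab share one code path.

Per stride of duration T, foot contact at t₀, duty factor d:

* **impact transients**: a Gaussian kernel (σ = 35 ms) at each ipsilateral
  contact, 0.55–0.7× as large at the contralateral contact (t₀ + T/2), and a
  negative kernel (σ = 45 ms) at foot off (t₀ + d·T). These carry the event
  timing that the detector must recover.
* **harmonics** at stride (1/T) and step (2/T) frequency, phase-locked to the
  contact. These carry the cadence information the PSD stage estimates.
* **white noise** at 5–6% of the walking amplitude.

Stride durations are truncated normal with the subject's mean and CV
(bounds 0.5–3.0 s); duty factors are truncated normal with CV 0.045 around
the subject's mean — chosen so bout-level duty-factor CV lands in the
0.04–0.05 range seen in free-living summaries. A profile with stride-time
CV = 0 denotes perfectly regular gait and switches off duty variability as
well. Event times are continuous floats on the segment's own time base and
are exact by construction; detection error is therefore measured in samples
against them.

The chest AP channel is rescaled so its RMS equals the profile's
`ap_amplitude` exactly (so RMS AP estimates regress on truth with slope 1).
Chest ML mixes stride-frequency sway with low-passed noise whose cutoff
scales with `ml_bandwidth`, making the spectral spread monotone in that
parameter. Non-gait filler is band-limited Gaussian noise at 10% of walking
amplitude plus ~1 posture-shift transient per minute.

### Cohort defaults

Baseline (non-faller) parameters, drawn per subject from truncated normals:

| parameter          | mean  | SD    | rationale                                   |
|--------------------|-------|-------|---------------------------------------------|
| stride time (s)    | 1.16  | 0.08  | free-living median for mildly impaired PwMS |
| stride-time CV     | 0.07  | 0.015 | free-living median ~0.067                   |
| duty factor        | 0.62  | 0.012 | free-living median                          |
| AP amplitude (g)   | 0.15  | 0.02  | non-faller median RMS AP; ~13% between-subject CV |
| ML bandwidth (Hz)  | 0.60  | 0.08  | Freqd ML scale                              |

Fallers are the same draws multiplied by the default effect configuration:
AP amplitude × 0.867 and duty factor × 0.984 — the ratios of the published
faller/non-faller medians (0.13/0.15 and 0.61/0.62), i.e. effects in the
clinically observed directions at clinically observed magnitudes. Survey
scores (ABC, EDSS, MFIS, MSWS, NSI) are drawn from the per-group demographic
means/SDs and clipped to instrument ranges; two NSI entries are blanked per
cohort (≥ 10 subjects) to exercise the k-NN imputation path.

Bout durations are 4-s-quantized: short ∈ {4, 8} s, medium ∈ {12…28} s,
long ∈ {32…120} s, drawn from the mixture 0.61/0.32/0.07 by default. Bouts
and gaps start on 4-s boundaries so window labels are exact.

A **parameter-level sampler** (`sample_bout_parameters`) draws bout-level
feature estimates directly from a profile — stride and duty draws identical
to the signal model, summarized exactly as the feature stage summarizes
detected strides, plus class-dependent estimation noise (6/4/2.5% relative
for short/medium/long) on the signal-level features. It exists so
statistical experiments (null calibration, power, classifier nulls) can run
hundreds of cohorts in seconds; a calibration test checks it against the
full signal path.

## Stride detection

1. **Cadence**: Welch periodogram of the mean-removed thigh AP channel
   (10-s segments or the full bout if shorter, 50% overlap). Stride
   frequency = dominant peak in 0.4–1.3 Hz, with subharmonic
   disambiguation: if half the dominant frequency also carries a peak
   (≥ 10% of the dominant power and above the noise floor), the dominant
   peak was the step harmonic. The peak must exceed 10× the median in-band
   power, else the bout has no cadence and is removed. Step frequency =
   dominant peak within ±20% of twice the stride frequency. Peak locations
   are refined by parabolic interpolation.
2. **Filter bank**: 4th-order zero-phase Butterworth band-passes at ±20%
   relative bandwidth around the stride and step frequencies.
3. **Events**: an *event signal* is formed as the low-passed AP
   (cutoff 4× step frequency) minus the two narrowband outputs; this keeps
   the sharp impact/swing-initiation transients while removing the
   harmonics' own extrema. Foot contacts are event-signal peaks lying in
   the positive half-cycle of the stride-band signal (one per cycle;
   largest wins, earliest on ties). Foot offs are the event-signal trough
   in [0.45, 0.82] of each contact-to-contact interval — the window excludes
   the contralateral contact (0.5 reached only at extreme duty) and the
   ringing that precedes the next impact. Parabolic refinement gives
   sub-sample timing.

On the synthetic oracle this recovers stride times with MAE ≈ 0.25 samples
and foot contacts with median error ≈ 0.13 samples across stride times
0.8–1.8 s, and duty factor to within ±0.01.

Validity ranges (our own; the filtering rule "physiologically impossible"
has no published bounds): stride time 0.5–3.0 s, duty factor 0.45–0.85,
stance and swing ≥ 0.1 s; bouts need ≥ 2 strides before and after
stride-level removal. Every filter logs (n_before, n_removed, n_after).

## Features

* **RMS AP** — RMS of the mean-removed chest AP channel, reported in g.
  (Published tables footnote the unit as √g; we treat that as a
  typographical artifact and report g.)
* **Freqd ML** — "frequency dispersion" has no closed formula in the gait
  literature summaries it appears in; we adopt the PSD-weighted spectral
  standard deviation, √(ΣP(f)(f−f̄)²/ΣP(f)) over (0, fs/2], which carries
  the Hz unit the tables print. White noise gives (fs/2)/√12 ≈ 4.51 Hz at
  31.25 Hz; a pure tone gives ~0.
* **Entropy ratio** — sample entropy (m = 2, r = 0.2·SD, Chebyshev
  distance, self-matches excluded) of the mean-removed resultant
  acceleration, thigh over chest; computed for long bouts. Series are
  truncated at 2000 samples (~64 s) to keep the quadratic template search
  cheap; the truncation applies identically to both sensors.
* **Largest Lyapunov exponent** — Rosenstein divergence-curve method:
  delay embedding (dimension 5; delay = first autocorrelation minimum
  capped at ¼ stride period), nearest neighbour outside a one-stride-period
  Theiler window, mean log divergence fit over 0–0.5 stride periods,
  slope in 1/s. Computed on the chest AP and ML channels of lab bouts
  (any > 60 s bout supports it via a flag). *Caveat*: on the synthetic
  signals the estimate is dominated by the white measurement noise and is
  an order of magnitude larger than values reported for real trunk
  acceleration; only the property-level behaviour (≈ 0 for noiseless
  periodic signals, monotone in added noise) is claimed.

Feature arity is a function of bout class alone: 8 (short/medium/all-home),
9 (long, + entropy ratio), 11 (lab, + both Lyapunov exponents); partial
vectors are never emitted.

## Statistics

Wilcoxon rank-sum tests are two-sided: exact enumeration when min(n) ≤ 8
and the pooled sample is tie-free, tie-corrected normal approximation
otherwise (identical samples short-circuit to p = 1). All suites run at
α = 0.05 with no multiplicity correction, matching the analysis they
mirror; a Benjamini–Hochberg helper exists but is off by default.
Percentiles use linear interpolation between order statistics. Units of
analysis: pooled bout-level values for the duration and context suites,
per-subject summary statistics for the faller suite (whose rows are named
summary statistics). Subject summaries with no bouts in a class simply drop
out of that class's tests.

k-NN survey imputation: a missing value is the mean of the field over the
k = 3 nearest complete rows by Euclidean distance on the z-scored remaining
survey fields (z-statistics from the complete rows; stable ordering breaks
distance ties).

## Classifiers

Feature-based: per LOSO fold, StandardScaler + PCA (smallest component
count explaining ≥ 95% of training variance) + model, all fit on training
rows only. Families: logistic regression, RBF-SVM (probability outputs),
decision tree, k-NN (neighbour count capped at the training size), random
forest. Seeded random hyperparameter search with grouped inner CV is
available (`n_search` draws); it defaults to off so the standard runs use
library defaults. AUC is computed in-package as the Mann–Whitney pair
statistic (ties ½) and is cross-checked against an independent
implementation in the tests. Positive class = faller throughout.

Sequence-based: inputs are k consecutive strides of raw 6-channel
acceleration (chest v/ml/ap then thigh v/ml/ap), sliced foot-contact to
foot-contact and concatenated — a step-1 sliding window over each bout's
stride sequence (disjoint blocks selectable). The subject's ABC score can
ride along as a constant seventh channel. Models are stacked (Bi)LSTM
layers with inter-layer dropout and a dense softmax on the last valid
timestep, trained with Adam on masked variable-length batches; the
implementation is pure numpy, driven by one seeded generator, so training
is bit-reproducible. Reference architectures: LSTM 2 (LSTM 290 → 30%
dropout → BiLSTM 10 → 40% dropout, 55 epochs) and LSTM 3 (LSTM 85/85/235
with 55/55/45% dropout, 125 epochs); experiments at package scale use a
reduced single-layer LSTM (16 units, ~5 epochs). Evaluation is a modified
LOSO — one test subject, one validation subject chosen by fixed cyclic
rotation (the next subject id), remainder training — so no subject spans
partitions; scores are pooled per input and median-aggregated per subject.

## Problem sizes

The experiments are sized for a single CPU: simulated wear time of 8–15
minutes per subject (the bout mixture, not the total hours, drives every
downstream stage), cohorts of 10–38 subjects, 100–200 replicates for power
and null-calibration checks, and the reduced sequence architecture for
LOSO training. The window classifier trains on a few hundred windows from
6 training subjects and is evaluated on held-out subjects.

## What the synthetic experiments show — and don't

Passing tests establish that each stage implements its contract: events are
recovered to sub-sample accuracy *on the stated signal model*, features
match their closed forms, the statistical machinery is calibrated (null
false-positive rate ≈ α, permutation-null AUC ≈ 0.5), injected group
effects of clinical magnitude are detected with high power at 21-vs-17
subjects, and the pipeline is bit-deterministic under a seed. They do not
establish clinical performance: real thigh/chest acceleration has richer
morphology (turns, stairs, assistive devices, sensor misalignment — all
explicitly outside the generator), the real activity classifier was trained
on heterogeneous clinical corpora, and published AUCs (≈ 0.6–0.8) reflect
dataset difficulty that a synthetic cohort with configured effects does not
reproduce. Classifier AUCs on synthetic cohorts should be read as
learnability checks, not performance claims.

## Known limitations

* Binary gait/non-gait only; no turn, stair, or transition classes.
* Single-limb events (right thigh); no bilateral attribution.
* No gait speed or distance-calibrated metrics (accelerometry only).
* The non-gait filler is a stand-in; the spectral shape of real non-gait
  activity is not modelled.
* Lyapunov magnitudes on synthetic data are noise-dominated (see above).
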