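# Methods

`chaosaudio` classifies *auditory household chaos* — a four-level ordinal
scale applied to 5-second windows of daylong child-worn home audio — and
provides the annotation-triage detector and evaluation protocol that make
building such a classifier practical when high-chaos moments are rare.
This note documents the models, the numerical conventions, the synthetic
data the package is validated on, and the design choices made where the
problem left the design open.

## The segment contract

All analysis operates on non-overlapping, contiguous 5-s segments of
mono audio at 22,050 Hz (110,250 samples).  Arbitrary WAV input is mixed
down and resampled (polyphase, `scipy.signal.resample_poly`) on load; a
trailing remainder shorter than 5 s is dropped, so a recording of
duration `d` yields `floor(d / 5)` segments — one hour is exactly 720
segments, and a 411.2-hour corpus is exactly 296,064.  Time coordinates
are 0-based and half-open.

Framewise features share one convention: window 512 samples, hop 256,
*centered* (zero padding of half a window on each side).  Centered
framing is what makes a 5-s segment yield `1 + floor(110250/256) = 431`
frames; the uncentered convention would give 429 and is not used.

## Features

* **Frame RMSE** — root-mean-square energy per frame.  Participant-level
  loudness context is the grand mean of all frame RMSE values over the
  *entire* recording; the detector's rules are expressed as multiples
  (3x, 7x) of that mean, which makes them robust to per-device gain.
* **Spectral flatness** — geometric/arithmetic mean ratio of the Hann
  power spectrum, per frame; ~1 for noise, ~0 for tones.  Each frame's
  spectrum is floored at 1e-10 of its own peak, making the statistic
  scale-invariant and giving a line spectrum flatness far below the
  detector's 1e-4 threshold at any amplitude.  All-zero frames read 1
  ("silence is flat").  The one or two outermost frames of a segment are
  zero-padded half-frames whose truncation splatter can exceed 1e-4 even
  for a pure tone; the detector's noise signature requires *all* frames
  above threshold, so this does not affect decisions.
* **Zero crossings** — segment-level count of sign transitions over the
  full 5 s.  Runs of exact zeros between opposite signs count as one
  crossing; zeros between equal signs count none.  The framewise
  zero-crossing *rate* used in the 53-feature vector applies the same
  rule within each frame, divided by (window − 1).
* **MFCCs** — 20 coefficients from a 40-band triangular mel filter bank
  (HTK mel scale, 0 Hz to Nyquist, FFT size = window size), natural log
  with an absolute floor of 1e-10, orthonormal DCT-II.  The filter-bank
  parameters are fixed here by configuration; nothing in the framing
  contract pins them.
* **Spectral centroid / bandwidth / rolloff** — magnitude-weighted mean
  frequency, its weighted standard deviation, and the 85%-energy
  frequency, per frame; silent frames score 0.
* **Feature vectors** — `extract_features3` is the volume baseline
  (mean RMSE, std RMSE, peak amplitude).  `extract_features53` stacks
  the mean and standard deviation across frames of 26 framewise features
  (20 MFCCs, zero-crossing rate, flatness, rolloff, centroid, bandwidth,
  RMSE) plus peak amplitude: 26×2 + 1 = 53, in the documented order
  (all means, all stds, peak last).
* **Log-mel patches** — each 5-s segment is chunked into 2-s patches
  (2 s, 2 s, 1-s tail replicated to 2 s); each patch becomes a 96-band
  log-mel matrix with a 40-ms window (882 samples) and 50% overlap,
  giving 96×101 per patch.  Log floor 1e-10, mel range 0–11,025 Hz.

## The high-chaos detector

High chaos (level 3) is rare in daylong audio (~2% in unfiltered data),
so annotating uniform samples is wasteful.  The detector flags candidate
segments from the output of an external everyday-sound classifier
(consumed as (class, confidence) tables; the package never requires the
classifier itself):

1. **Class grouping.**  Each retained sound class maps to `high` or
   `non_high` chaos.  Classes with an annotation-quality estimate at or
   below 33%, or marked excluded (implausible in home recordings), are
   dropped.  The shipped table covers the documented example classes and
   a small extension list; a full mapping is user-supplied CSV.
2. **Confidence pruning.**  Top-10 predictions per segment, discarding
   confidence below 0.01% (1e-4 on the [0,1] scale, inclusive floor).
3. **Cry/babble disambiguation.**  Infant cries and babbles are commonly
   confused by sound-event models.  When both appear: if any frame RMSE
   exceeds 3x the participant mean, keep cry and drop babble (crying is
   loud); otherwise the reverse.  The comparison uses raw frame RMSE.
4. **White-noise/vehicle disambiguation.**  Sleep-aid white noise is
   commonly mislabeled as vehicles.  If all flatness frames exceed 1e-4
   *or* the zero-crossing count lies in [1000, 4000], and a vehicle-like
   class is predicted, the vehicle-like prediction is removed.  The rule
   is read as `(flatness-all OR zc-band) AND vehicle-like`, and "drop"
   removes the prediction, not the segment — both readings are
   switchable (`drop_segment=True` empties the segment's predictions).
5. **Candidate rule.**  A segment is a candidate iff a surviving
   prediction maps to `high`, or any frame RMSE exceeds 7x the
   participant mean (the loudness override, which applies even to
   segments with no predictions at all).

Efficiency is scored on level-3 ground truth: recall, precision,
candidate fraction, and the *enrichment factor* — the high-chaos rate in
the candidate set divided by the rate in a size-matched random sample.
On synthetic streams with miss rate *m*, false-alarm rate *f* and
prevalence *p*, prediction-only detection obeys recall = 1 − m and
precision = p(1−m) / (p(1−m) + (1−p)f); this closed form is verified by
Monte-Carlo in the tests (the loudness override, when audio is present,
adds recall beyond 1 − m by construction and is tested separately).

## Classifiers

* **RF-3f** — random forest (1000 trees, seeded) on the 3 volume
  features.  Deliberately weak: it quantifies how far loudness alone
  goes.
* **RF-53f** — the same forest on the 53 classical features.
* **CNN** — over the 96×101 log-mel patches: three 5×5 convolutions with
  pre-activation batch normalization (BN → ReLU → conv), two max-pools
  interleaved between the convolutions, then two dense layers; softmax
  over the four levels.  Categorical cross-entropy, batch size 64, Adam
  at learning rate 0.001, early stopping on validation accuracy with
  patience 15 and best-weights restoration; `max_epochs` additionally
  bounds the loop.  The network is implemented directly on numpy
  (im2col convolutions, float32), with analytic gradients verified
  against float64 finite differences in the test suite.

  Channel widths and pool sizes are free design knobs (only the layer
  counts, kernel size and ~0.5M weight budget are fixed).  The defaults
  — widths 4/8/16, pools 4×4 then 2×2, dense width 200 — put the
  parameter mass in the first dense layer (465,958 trainable parameters,
  within the enforced [0.3M, 0.7M] bound) while keeping convolutional
  compute low enough for CPU training.  A 4×4 first pool reduces the
  mel axis to 24 bands early; the synthetic classes (and, plausibly,
  coarse chaos structure generally) are separable at that resolution.

  Validation split for early stopping: participant-grouped 10% when at
  least 5 training participants exist; otherwise a class-stratified
  random 10% of patches (small LOPO cohorts leave too few participants
  for a grouped split).

  Segment-level prediction aggregates the per-patch probability vectors
  by element-wise geometric mean (floored at 1e-12 so one zero cannot
  annihilate a class), renormalized; argmax ties break to the *lowest*
  chaos level (conservative).

## Evaluation protocol

* **Balanced training sets.**  Per LOPO fold, an equal per-class time
  budget is drawn from the non-test participants.  Level 0 (silence) is
  the repetition class: every available segment is included once, then
  topped up with replacement to the budget (repetition cannot change
  what silence is); if the level-0 pool already exceeds the budget, a
  plain without-replacement draw is used, since "every segment at least
  once" is unsatisfiable inside the budget.  All other classes are
  unique draws, and a pool smaller than the budget is a hard
  `ShortfallError`.  `default_budget_hours` generalizes the budget rule:
  the minimum available non-test hours over the non-repetition classes,
  floored to a configurable granularity.
* **LOPO-CV.**  One fold per participant; the fold's training manifest
  never contains test-participant segments (asserted at run time); fold
  predictions are pooled for global metrics.
* **Metrics.**  Global macro (unweighted class mean) and weighted
  (support-weighted) precision/recall/F1 plus a full 4×4 confusion
  matrix.  Classes absent from both truth and predictions are excluded
  from the macro average rather than scored zero, and reported.
  Participant-specific weighted scores are computed within each
  participant's own test set and feed two-sided paired t-tests at
  α = 0.05, uncorrected; a zero-variance difference vector is flagged as
  degenerate (identical scores give t = 0, p = 1).
* **Cry/non-cry split.**  Segments carrying a cry-like sound-event
  prediction form the Cry set; segments *predicted* level 0 are dropped
  from it before scoring (that class is essentially absent there and
  would distort macro metrics); the Non-cry set is the complement.
* **Ablation.**  A grid of exponentially decreasing total balanced sizes
  with several seeded runs per size; run *r* shares its sampling seed
  across sizes (shared folds per seed, for variance reduction).  Sizes a
  dataset cannot support are recorded as skipped rather than aborting.

## Synthetic soundscapes

The generator exists to make the pipeline testable end to end without
the gated recordings; it emulates the *structure* of the problem, not
home acoustics.  Chaos levels map to synthesis recipes spanning the
annotation scheme qualitatively:

| level | recipe | loudness (default regime) |
|---|---|---|
| 0 | near-silence, peak ≤ 0.01 | — |
| 1 | one smooth source: low tone (200–600 Hz) or steady white noise | peak 0.05–0.15 |
| 2 | harmonic stack (3–6 partials) + speech-like AM noise (3–8 Hz) | peak 0.25–0.45 |
| 3 | 3–5 overlapping sources, always including a decaying click train | peak 0.55–0.9 |

All randomness flows from explicit seeds; identical (spec, seed) gives
bit-identical waveforms, and recordings synthesize segments lazily from
stored specs (an hour of float64 audio is ~300 MB; features are banked,
audio discarded).

**Volume-confounded regime.**  To reproduce the qualitative claim that
loudness alone cannot separate the levels, the confounded mode actively
decouples volume from class for levels 1–3: each mixed waveform is
envelope-whitened at ~50 ms resolution, waveshaped with a random
exponent (randomizing crest factor), modulated by a random slow AM
envelope, and scaled to a target RMS drawn log-uniformly from one shared
range (0.02–0.25).  Loud-but-calm (level-1 white noise at high gain) and
quiet-but-cacophonous (level-3 mixtures at low gain) segments then both
occur by construction.  Level 0 remains silence — by definition it is
separable by volume, so "volume-only ≈ chance" holds on the three
non-silent levels (a forest over the 3 volume features scores near the
1/3 chance F1 there), while spectral models stay near ceiling.

**Prediction-table noise model.**  Synthetic (class, confidence) tables
use the shipped class map's names.  True level-3 segments carry a
high-group class (confidence 0.4–0.95) with probability 1 − miss_rate;
lower levels with probability false_alarm_rate; 1–9 filler non-high
classes get confidences 1e-5–0.3, some deliberately below the 1e-4
floor.  Error-mode knobs: cry↔babble co-prediction and white-noise →
vehicle confusion (the confusions the acoustic pruning rules exist to
fix).  Defaults (miss 0.35, false alarm 0.037, cry/babble 0.2,
white-noise/vehicle 0.5) place the detector in the published operating
regime — recall ~0.5–0.65, precision ~0.2, enrichment ≫ 1 at 2%
prevalence — without being fit to any particular number.

**What passing does and does not show.**  The synthetic classes are
spectrally well separated and stationary within a segment; real home
audio is not.  Passing the recovery experiments demonstrates that the
pipeline — features, balanced sampling, training, aggregation, LOPO
bookkeeping, metrics — is correct and leak-free, and that the model
ordering (spectral models ≫ volume baseline under confounding) has the
expected direction.  It does not certify real-world accuracy numbers.

## Desk-scale experiment sizes

The recovery and ablation experiments run on a 4-participant cohort with
0.5 h per participant (2 h of audio, 1,440 segments), per-fold balanced
budgets of 0.025 h/class, at most 12 CNN training epochs, and an
ablation grid of {0.4, 0.2, 0.1, 0.05} total hours (3 runs x 4 sizes =
12 experiments; the grid runs RF-53f — the harness is model-agnostic).
These are 1/100-scale analogues of a 40-hour balanced design, chosen so
the full protocol (including three CNN LOPO-CV runs) completes in
minutes on one CPU core.

## Known limitations

* The shipped class map is a few dozen classes, not a full sound-event
  taxonomy; real deployments supply their own CSV.
* The synthetic generator's "cacophony" operationalization (source
  count + overlap + impulsiveness) is a stand-in; no claim is made that
  it matches how human annotators weigh real scenes.
* MFCC filter-bank parameters, mel/log floors and the rolloff fraction
  are configuration choices, not recovered constants; swapping them
  changes feature values (but not the framing laws or dimensionalities).
* The numpy CNN targets small, CPU-scale experiments; it is not a
  performance-parity reimplementation of a DL framework.
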