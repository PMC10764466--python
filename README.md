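# chaosaudio

Household chaos — noisy, crowded, unpredictable home environments — is a
well-replicated correlate of child development outcomes, but it is
usually measured by one-off parent questionnaires.  `chaosaudio` is a
toolkit for measuring its *auditory* component objectively and at high
resolution from daylong child-worn audio recorders: every 5-second
segment of audio gets an ordinal **chaos level**

| level | meaning |
|---|---|
| 0 | silence / absence of sounds |
| 1 | soft daily or familiar sounds |
| 2 | slightly stimulating sounds |
| 3 | highly stimulating, scary or jarring sounds |

The package implements the full modeling stack for researchers in
developmental science and digital-health sensing:

* **Annotation triage.**  High-chaos moments are rare (~2% of daylong
  audio), so a *high-chaos detector* flags candidate segments for human
  annotation from the output of any everyday-sound classifier
  (consumed as `(class, confidence)` tables), using class grouping,
  confidence pruning, cry/babble and white-noise/vehicle disambiguation
  heuristics, and a participant-relative loudness override
  (frame RMSE > 7x the participant's mean).  Efficiency is reported as
  recall/precision on level-3 ground truth and as the *enrichment
  factor* over a size-matched random sample.
* **Three chaos classifiers.**  A volume-only baseline (random forest on
  mean/std frame RMSE + peak amplitude, "RF-3f"), a classical
  acoustic-feature forest (53 features: mean+std of 20 MFCCs,
  zero-crossing rate, spectral flatness/rolloff/centroid/bandwidth,
  RMSE, plus peak amplitude — "RF-53f"), and a compact CNN (~0.5M
  weights; three 5x5 pre-activation BN convolutions, two max-pools, two
  dense layers) over 2-s, 96-band log-mel patches, whose per-patch
  probabilities are combined by element-wise geometric mean.
* **Evaluation protocol.**  Class-balanced training-set construction
  (level-0 oversampled with repetition, other levels unique draws),
  leave-one-participant-out cross-validation with leakage assertions,
  global macro/weighted metrics with confusion matrices,
  participant-specific weighted scores with paired t-tests, cry/non-cry
  splits, and a data-ablation grid.
* **Synthetic soundscapes.**  A seeded generator of labeled 4-level
  scenes (tones, harmonic stacks, speech-like AM noise, white noise,
  impulsive click trains) and of noisy sound-event prediction tables,
  including a *volume-confounded* regime in which loudness carries no
  class information — so every claim the package makes is testable
  without access to gated recordings.

The framing conventions are load-bearing and enforced: 22,050 Hz mono,
5-s segments of 110,250 samples (an hour is 720 segments), and centered
sliding windows of 512 samples with hop 256, giving exactly 431 frames
per segment.

## Worked example

Simulate a quarter hour of labeled audio with realistic rarity of high
chaos, then run the detector over its (noisy) sound-event predictions:

```bash
$ chaos simulate --hours 0.25 --prevalence 0.25,0.40,0.33,0.02 --seed 7 --out demo
wrote 180 segments: demo/P01.wav, demo/P01_labels.csv, demo/P01_predictions.jsonl

$ chaos detect --predictions demo/P01_predictions.jsonl --audio demo/P01.wav \
    --out demo/candidates.csv
9/180 candidates -> demo/candidates.csv
```

The 180 segments contain 3 true level-3 segments; the detector flags 9
candidates of which 2 are truly high chaos — so instead of annotating
all 15 minutes, an annotator reviews 45 seconds and still sees most of
the high-chaos material (the candidate set is ~13x richer in high chaos
than the stream).  The same logic is available as a library
(`chaosaudio.detector`), and `chaos train` / `chaos predict` /
`chaos evaluate` / `chaos ablate` cover the modeling side:

```python
from chaosaudio import pipeline

cohort = pipeline.build_cohort(4, 0.5, seed=101)          # 2 h, 4 participants
cv = pipeline.run_recovery_experiment("cnn", cohort, seed=0)
print(cv.report.macro)   # {'precision': 0.969, 'recall': 0.967, 'f1': 0.967}
```

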