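"""End-to-end experiment assembly on synthetic cohorts.

Glue between the synthetic generator and the evaluation harness:
synthesize a multi-participant cohort, extract every model's inputs
(volume features, 53-feature vectors, log-mel patch sets) segment by
segment — raw audio is discarded as soon as its features are banked —
and run the balanced-sampling -> model -> LOPO-CV recovery experiments
and the detector-efficiency experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classmap, detector, evaluation, models, synthetic
from .features import extract_features3, extract_features53, logmel_patches

BALANCED_PREVALENCE = (0.25, 0.25, 0.25, 0.25)

# Desk-scale study conditions for the synthetic recovery experiments: a
# 4-participant cohort with 0.5 h per participant (2 h of audio), balanced
# per-fold training budgets of 0.025 h per class, and an ablation grid
# proportional to the 40/20/10/5-hour design at 1/100 scale.
DESK_PARTICIPANTS = 4
DESK_HOURS_EACH = 0.5
DESK_BUDGET_HOURS_PER_CLASS = 0.025
DESK_CNN_MAX_EPOCHS = 12
DESK_ABLATION_SIZES = (0.4, 0.2, 0.1, 0.05)  # total balanced hours
#: Rare-event prevalence for detector experiments: high chaos ~2% of
#: daylong audio, the regime that makes annotation triage worthwhile.
RARE_PREVALENCE = (0.25, 0.40, 0.33, 0.02)


@dataclass
class Cohort:
    """A synthetic multi-participant cohort with per-segment model inputs."""

    recordings: dict[str, synthetic.SyntheticRecording]
    dataset: pd.DataFrame  # participant_id, segment_id, chaos_level
    f3: dict[str, np.ndarray] = field(default_factory=dict)
    f53: dict[str, np.ndarray] = field(default_factory=dict)
    patches: dict[str, np.ndarray] = field(default_factory=dict)
    participant_of: dict[str, str] = field(default_factory=dict)


def build_cohort(
    n_participants: int,
    hours_each: float,
    prevalence: tuple[float, float, float, float] = BALANCED_PREVALENCE,
    seed: int = 0,
    confounded: bool = False,
    extract: bool = True,
) -> Cohort:
    """Synthesize a cohort and (optionally) extract all model inputs."""
    rng = np.random.default_rng(seed)
    recordings = {}
    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        rec = synthetic.generate_recording(
            pid, hours_each, prevalence, int(rng.integers(2**31 - 1)), confounded
        )
        recordings[pid] = rec
        for j in range(rec.n_segments):
            rows.append((pid, f"{pid}:{j}", int(rec.labels[j])))
    dataset = pd.DataFrame(rows, columns=["participant_id", "segment_id", "chaos_level"])
    cohort = Cohort(recordings=recordings, dataset=dataset)
    if extract:
        for pid, rec in recordings.items():
            for j in range(rec.n_segments):
                seg = rec.segment(j)
                sid = seg.segment_id
                cohort.f3[sid] = extract_features3(seg)
                cohort.f53[sid] = extract_features53(seg)
                cohort.patches[sid] = logmel_patches(seg).as_array().astype(np.float32)
                cohort.participant_of[sid] = pid
    return cohort


def model_factory_for(cohort: Cohort, model: str, cnn_max_epochs: int = DESK_CNN_MAX_EPOCHS):
    """A seeded classifier factory over the cohort's feature stores.

    ``model`` is one of ``rf3``, ``rf53``, ``cnn``.
    """
    if model == "rf3":
        return lambda seed: models.RFSegmentClassifier(
            cohort.f3, models.RFConfig(feature_set="f3", seed=seed)
        )
    if model == "rf53":
        return lambda seed: models.RFSegmentClassifier(
            cohort.f53, models.RFConfig(feature_set="f53", seed=seed)
        )
    if model == "cnn":
        return lambda seed: models.CNNSegmentClassifier(
            cohort.patches,
            models.CNNConfig(seed=seed, max_epochs=cnn_max_epochs),
            participant_of=cohort.participant_of,
        )
    raise ValueError(f"unknown model {model!r}; expected rf3, rf53 or cnn")


def run_recovery_experiment(
    model: str,
    cohort: Cohort,
    budget_hours_per_class: float = DESK_BUDGET_HOURS_PER_CLASS,
    seed: int = 0,
    cnn_max_epochs: int = DESK_CNN_MAX_EPOCHS,
) -> evaluation.CVResult:
    """Balanced sampling -> model -> LOPO-CV label recovery on a cohort."""
    plan = evaluation.BalancedPlan(
        per_class_budget_hours=budget_hours_per_class, seed=seed
    )
    factory = model_factory_for(cohort, model, cnn_max_epochs=cnn_max_epochs)
    return evaluation.lopo_cv(cohort.dataset, factory, plan)


def run_detector_experiment(
    hours: float = 4.0,
    prevalence: tuple[float, float, float, float] = RARE_PREVALENCE,
    noise: synthetic.PredictionNoiseSpec | None = None,
    seed: int = 0,
    with_audio: bool = True,
) -> detector.DetectorEfficiencyReport:
    """Detector efficiency on a synthetic daylong stream.

    Generates one labeled recording plus a noisy prediction table and
    runs the full detector.  With ``with_audio`` the per-segment frame
    features (RMSE, flatness, zero crossings) and the participant's
    grand mean RMSE are computed from the waveforms, so the acoustic
    pruning rules and the loudness override are active — in particular
    the flatness rule removes the white-noise->vehicle confusions the
    noise model injects.  Without audio the detector sees prediction
    tables alone (the regime of the Bayes recall/precision analysis).
    Scores recall/precision plus enrichment against a size-matched
    random sample.
    """
    from .features import frame_rmse, spectral_flatness_series, zero_crossings

    noise = noise or synthetic.PredictionNoiseSpec(seed=seed)
    rec = synthetic.generate_recording("P01", hours, prevalence, seed)
    table = synthetic.generate_prediction_table(rec, noise)
    group_map = detector.build_group_map(classmap.default_class_table())
    frame_features = stats = None
    if with_audio:
        frame_features = {}
        total, count = 0.0, 0
        from .features import ParticipantStats

        for i in range(rec.n_segments):
            seg = rec.segment(i)
            r = frame_rmse(seg)
            frame_features[seg.segment_id] = {
                "rmse": r,
                "flatness": spectral_flatness_series(seg),
                "zc": zero_crossings(seg),
            }
            total += r.values.sum()
            count += len(r)
        stats = ParticipantStats(rec.participant_id, total / count)
    results = detector.run_detector(
        table, group_map, frame_features=frame_features, stats=stats,
        segment_ids=rec.segment_ids,
    )
    truth = dict(zip(rec.segment_ids, (int(x) for x in rec.labels)))
    rng = np.random.default_rng(seed + 1)
    n_cand = int(results["is_candidate"].sum())
    sample = list(rng.choice(rec.segment_ids, size=min(n_cand, rec.n_segments), replace=False))
    return detector.evaluate_detector(results, truth, matched_random_sample=sample)
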