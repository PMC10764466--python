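"""Evaluation protocol: balanced training sets, LOPO-CV, metrics, ablation.

The protocol mirrors how wearable-audio classifiers must be validated:
no test participant's audio may influence training, so models are
scored by leave-one-participant-out cross-validation (LOPO-CV).  For
each fold a class-balanced training set is drawn from the remaining
participants — an equal per-class time budget, sampled without
repetition except for the no-chaos class (silence), where every
available segment is included once and the remainder is topped up with
repetition.  Fold predictions are pooled into global macro and weighted
precision/recall/F1 plus a confusion matrix; participant-specific
weighted scores support paired t-tests between models; a data-ablation
grid retrains at shrinking budgets to price annotation volume.

Datasets are plain DataFrames with columns ``participant_id``,
``segment_id``, ``chaos_level`` (ints 0-3) and optionally
``source_set``.  One hour of audio is 720 segments, so an hour budget
converts to ``round(hours * 720)`` segments per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

SEGMENTS_PER_HOUR = 720
CHAOS_LEVELS = (0, 1, 2, 3)


class DatasetError(ValueError):
    """Raised for malformed annotation tables."""


class ShortfallError(ValueError):
    """Raised when a non-repetition class cannot fill its budget."""


def validate_dataset(dataset: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "segment_id", "chaos_level"}
    missing = required - set(dataset.columns)
    if missing:
        raise DatasetError(f"dataset missing columns: {sorted(missing)}")
    if dataset["segment_id"].duplicated().any():
        raise DatasetError("duplicate segment_id in dataset")
    if not dataset["chaos_level"].isin(CHAOS_LEVELS).all():
        raise DatasetError("chaos_level values must be in 0-3")
    return dataset


def hours_per_class(dataset: pd.DataFrame) -> pd.Series:
    """Annotated hours per chaos level (segments x 5 s / 3600)."""
    counts = dataset["chaos_level"].value_counts().reindex(CHAOS_LEVELS, fill_value=0)
    return counts * 5.0 / 3600.0


def default_budget_hours(
    dataset: pd.DataFrame,
    test_participant_id: str,
    with_repetition_classes: tuple[int, ...] = (0,),
    granularity_hours: float = 1.0,
) -> float:
    """Largest per-class budget the non-test pool can support.

    The budget is the minimum available hours over the classes sampled
    without repetition, floored to the configured granularity (the
    repetition classes can always be topped up).
    """
    pool = dataset[dataset["participant_id"] != test_participant_id]
    hrs = hours_per_class(pool)
    avail = min(hrs[c] for c in CHAOS_LEVELS if c not in with_repetition_classes)
    return float(np.floor(avail / granularity_hours) * granularity_hours)


# -- balanced training sets ------------------------------------------------


@dataclass(frozen=True)
class BalancedPlan:
    """Per-fold balanced sampling plan."""

    per_class_budget_hours: float = 10.0
    test_participant_id: str | None = None
    with_repetition_classes: tuple[int, ...] = (0,)
    seed: int = 0

    @property
    def n_per_class(self) -> int:
        return int(round(self.per_class_budget_hours * SEGMENTS_PER_HOUR))


def make_balanced_trainset(dataset: pd.DataFrame, plan: BalancedPlan) -> pd.DataFrame:
    """Draw a balanced training manifest (segment_id, chaos_level rows).

    Exactly ``plan.n_per_class`` segments per class, excluding the test
    participant.  Repetition classes (level 0 by default) include every
    pool segment at least once and top up with replacement; all other
    classes are unique draws, and a pool smaller than the budget raises
    :class:`ShortfallError`.  When a repetition class's pool already
    exceeds the budget, a plain without-replacement draw is used.
    """
    validate_dataset(dataset)
    rng = np.random.default_rng(plan.seed)
    pool = dataset[dataset["participant_id"] != plan.test_participant_id]
    n = plan.n_per_class
    parts = []
    for cls in CHAOS_LEVELS:
        cls_pool = pool[pool["chaos_level"] == cls]
        avail = len(cls_pool)
        if cls in plan.with_repetition_classes:
            if avail == 0:
                raise ShortfallError(f"class {cls}: no segments available")
            if avail <= n:
                extra = cls_pool.iloc[rng.integers(0, avail, size=n - avail)]
                parts.append(pd.concat([cls_pool, extra]))
            else:
                parts.append(cls_pool.iloc[rng.choice(avail, size=n, replace=False)])
        else:
            if avail < n:
                raise ShortfallError(
                    f"class {cls}: only {avail} segments ({avail / SEGMENTS_PER_HOUR:.2f} h) "
                    f"available for a budget of {n} ({plan.per_class_budget_hours} h)"
                )
            parts.append(cls_pool.iloc[rng.choice(avail, size=n, replace=False)])
    out = pd.concat(parts, ignore_index=True)
    return out.iloc[rng.permutation(len(out))].reset_index(drop=True)


# -- metrics ---------------------------------------------------------------


@dataclass
class EvalReport:
    """Global macro/weighted scores, per-class detail, confusion matrix."""

    macro: dict[str, float]
    weighted: dict[str, float]
    per_class: pd.DataFrame
    confusion: np.ndarray
    excluded_classes: tuple[int, ...] = ()
    per_participant: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        out = {
            "macro": self.macro,
            "weighted": self.weighted,
            "confusion": self.confusion.tolist(),
            "excluded_classes": list(self.excluded_classes),
        }
        if self.per_participant is not None:
            out["per_participant"] = self.per_participant.to_dict(orient="records")
        return out


def global_metrics(y_true, y_pred) -> EvalReport:
    """Macro and support-weighted precision/recall/F1 plus 4x4 confusion.

    Classes absent from both the truth and the predictions are excluded
    from the macro average (rather than scored zero) and reported in
    ``excluded_classes``; the confusion matrix always spans all four
    levels.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise DatasetError("y_true and y_pred must have equal length")
    present = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    excluded = tuple(c for c in CHAOS_LEVELS if c not in present)
    p, r, f, support = precision_recall_fscore_support(
        y_true, y_pred, labels=present, zero_division=0
    )
    mp, mr, mf, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="macro", zero_division=0
    )
    wp, wr, wf, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="weighted", zero_division=0
    )
    per_class = pd.DataFrame(
        {"chaos_level": present, "precision": p, "recall": r, "f1": f, "support": support}
    )
    return EvalReport(
        macro={"precision": float(mp), "recall": float(mr), "f1": float(mf)},
        weighted={"precision": float(wp), "recall": float(wr), "f1": float(wf)},
        per_class=per_class,
        confusion=confusion_matrix(y_true, y_pred, labels=list(CHAOS_LEVELS)),
        excluded_classes=excluded,
    )


def participant_weighted_scores(predictions: pd.DataFrame) -> pd.DataFrame:
    """Weighted P/R/F1 within each participant's own test set.

    ``predictions`` needs columns participant_id, y_true, y_pred.
    """
    rows = []
    for pid, grp in predictions.groupby("participant_id", sort=True):
        rep = global_metrics(grp["y_true"], grp["y_pred"])
        rows.append(
            {
                "participant_id": pid,
                "precision": rep.weighted["precision"],
                "recall": rep.weighted["recall"],
                "f1": rep.weighted["f1"],
                "n_segments": len(grp),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    p_value: float
    degenerate: bool = False


def paired_model_test(scores_a, scores_b) -> PairedTestResult:
    """Two-sided paired t-test on participant-specific weighted scores.

    Requires the same participants in the same order.  A zero-variance
    difference vector is degenerate: identical scores give (t=0, p=1);
    a constant non-zero difference is flagged with an infinite statistic.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test requires at least 2 participants")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedTestResult(0.0, 1.0, degenerate=True)
        return PairedTestResult(float(np.sign(d.mean()) * np.inf), 0.0, degenerate=True)
    t, p = sps.ttest_rel(a, b)
    return PairedTestResult(float(t), float(p))


# -- LOPO-CV ---------------------------------------------------------------


@dataclass
class CVResult:
    """Pooled LOPO-CV output: per-segment predictions plus the report."""

    predictions: pd.DataFrame  # participant_id, segment_id, y_true, y_pred
    report: EvalReport
    fold_manifests: dict[str, pd.DataFrame] = field(default_factory=dict)


def lopo_cv(
    dataset: pd.DataFrame,
    model_factory,
    plan: BalancedPlan,
) -> CVResult:
    """Leave-one-participant-out cross-validation.

    One fold per participant: a balanced training set is drawn from the
    other participants (per ``plan``, with a fold-specific seed), a
    fresh model from ``model_factory(seed)`` is fitted on it, and the
    held-out participant's full data is predicted.  Fold predictions
    are pooled for the global report; per-participant weighted scores
    ride along.  Training manifests are retained, and a leakage
    assertion guarantees no test segment appears in its fold's manifest.
    """
    validate_dataset(dataset)
    participants = sorted(dataset["participant_id"].unique())
    if len(participants) < 2:
        raise DatasetError("LOPO-CV requires at least 2 participants")
    all_preds = []
    manifests: dict[str, pd.DataFrame] = {}
    for i, pid in enumerate(participants):
        fold_seed = int(plan.seed + 1000 * i)
        fold_plan = replace(plan, test_participant_id=pid, seed=fold_seed)
        train = make_balanced_trainset(dataset, fold_plan)
        test = dataset[dataset["participant_id"] == pid]
        assert not set(train["segment_id"]) & set(test["segment_id"]), (
            f"participant {pid}: test segments leaked into training manifest"
        )
        model = model_factory(fold_seed)
        model.fit(train["segment_id"].tolist(), train["chaos_level"].to_numpy())
        y_pred = model.predict(test["segment_id"].tolist())
        all_preds.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "segment_id": test["segment_id"].to_numpy(),
                    "y_true": test["chaos_level"].to_numpy(),
                    "y_pred": np.asarray(y_pred),
                }
            )
        )
        manifests[pid] = train
    predictions = pd.concat(all_preds, ignore_index=True)
    report = global_metrics(predictions["y_true"], predictions["y_pred"])
    report.per_participant = participant_weighted_scores(predictions)
    return CVResult(predictions=predictions, report=report, fold_manifests=manifests)


# -- cry / non-cry split ---------------------------------------------------


def split_cry_noncry(
    dataset: pd.DataFrame,
    cry_segment_ids,
    predicted_levels: pd.Series | dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a dataset into Cry / Non-cry evaluation sets.

    ``cry_segment_ids`` are the segments carrying a cry-like prediction
    in the sound-event table.  The Cry set additionally drops segments
    *predicted* as level 0 (too few such segments exist there to score
    that class meaningfully); the Non-cry set is the untouched
    complement, so before the level-0 drop the two sets partition the
    dataset.
    """
    validate_dataset(dataset)
    cry_ids = set(cry_segment_ids)
    pred = pd.Series(predicted_levels)
    is_cry = dataset["segment_id"].isin(cry_ids)
    cry = dataset[is_cry]
    keep = [sid for sid in cry["segment_id"] if pred.get(sid, -1) != 0]
    return cry[cry["segment_id"].isin(keep)], dataset[~is_cry]


# -- data ablation ---------------------------------------------------------


@dataclass(frozen=True)
class AblationGrid:
    """Training-size grid: sizes are *total* balanced hours (4 classes)."""

    training_sizes_hours: tuple[float, ...] = (40.0, 20.0, 10.0, 5.0)
    runs_per_size: int = 3
    seed: int = 0

    @property
    def n_runs(self) -> int:
        return len(self.training_sizes_hours) * self.runs_per_size


def run_ablation(
    dataset: pd.DataFrame,
    grid: AblationGrid,
    model_factory,
    with_repetition_classes: tuple[int, ...] = (0,),
) -> pd.DataFrame:
    """Retrain/evaluate over the size grid: one LOPO-CV per (size, run).

    Run ``r`` shares its sampling seed across all sizes (shared folds
    per seed, for variance reduction), so the 3x4 default grid performs
    12 LOPO-CV experiments.  Sizes the dataset cannot support are
    skipped with a warning column rather than aborting the grid.

    Returns one row per run: size, run index, seed, pooled macro and
    weighted metrics.
    """
    rows = []
    for size in grid.training_sizes_hours:
        per_class = size / len(CHAOS_LEVELS)
        for run in range(grid.runs_per_size):
            run_seed = int(grid.seed + 7919 * run)
            plan = BalancedPlan(
                per_class_budget_hours=per_class,
                with_repetition_classes=with_repetition_classes,
                seed=run_seed,
            )
            try:
                cv = lopo_cv(dataset, model_factory, plan)
            except ShortfallError as exc:
                rows.append(
                    {
                        "size_hours": size,
                        "run": run,
                        "seed": run_seed,
                        "skipped": str(exc),
                    }
                )
                continue
            rows.append(
                {
                    "size_hours": size,
                    "run": run,
                    "seed": run_seed,
                    "macro_f1": cv.report.macro["f1"],
                    "macro_precision": cv.report.macro["precision"],
                    "macro_recall": cv.report.macro["recall"],
                    "weighted_f1": cv.report.weighted["f1"],
                    "weighted_precision": cv.report.weighted["precision"],
                    "weighted_recall": cv.report.weighted["recall"],
                    "skipped": "",
                }
            )
    return pd.DataFrame(rows)


def ablation_summary(runs: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics per training size, sorted ascending in size."""
    ok = runs[runs["skipped"] == ""]
    return (
        ok.groupby("size_hours")[["macro_f1", "weighted_f1"]]
        .mean()
        .sort_index()
        .reset_index()
    )
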