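"""High-chaos candidate detector for annotation triage.

High-chaos (level 3) moments are rare in daylong home recordings, so
annotating uniformly sampled audio wastes most annotator time.  The
detector flags *candidate* segments for manual annotation using the
output of an external everyday-sound classifier plus loudness/spectral
heuristics:

1. keep each segment's top-10 predictions with confidence >= 0.01%;
2. disambiguate cry vs. babble co-predictions by participant-relative
   loudness (any frame RMSE above 3x the participant's mean RMSE keeps
   cry and drops babble; otherwise the reverse);
3. drop vehicle-like predictions on segments whose spectral-flatness
   profile or zero-crossing count marks them as steady noise (white
   noise machines are routinely mislabeled as vehicles);
4. flag the segment if any surviving prediction maps to the high-chaos
   class group, or — irrespective of predictions — if any frame RMSE
   exceeds 7x the participant mean (the loudness override).

Efficiency is quantified against ground truth as recall/precision on
level-3 labels and as the enrichment of true high chaos in the candidate
set relative to a size-matched random sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FrameSeries, ParticipantStats

QUALITY_THRESHOLD = 0.33
TOP_K = 10
MIN_CONFIDENCE = 1e-4  # "0.01% confidence" on the [0,1] score scale
FLATNESS_THRESHOLD = 1e-4
ZC_BAND = (1000, 4000)
CRY_RMSE_MULTIPLE = 3.0
LOUDNESS_RMSE_MULTIPLE = 7.0


class ClassMapError(ValueError):
    """Raised when class metadata is incomplete or inconsistent."""


@dataclass(frozen=True)
class ChaosGroupMap:
    """Retained class -> chaos-group mapping plus heuristic class sets."""

    group: dict[str, str]  # class_name -> {"high", "non_high"}
    vehicle_like: frozenset[str] = frozenset()
    cry_like: frozenset[str] = frozenset()
    babble_like: frozenset[str] = frozenset()

    def is_high(self, class_name: str) -> bool:
        return self.group.get(class_name) == "high"

    def __len__(self) -> int:
        return len(self.group)


def build_group_map(
    class_table: pd.DataFrame, quality_threshold: float = QUALITY_THRESHOLD
) -> ChaosGroupMap:
    """Build the detector's class map from a class-metadata table.

    Classes with quality estimate at or below the threshold, or marked
    excluded, are dropped.  Every retained class must carry a group
    assignment (``high`` / ``non_high``).
    """
    df = class_table
    required = {"class_name", "quality_estimate", "excluded", "chaos_group"}
    missing = required - set(df.columns)
    if missing:
        raise ClassMapError(f"class table missing columns: {sorted(missing)}")
    kept = df[(df["quality_estimate"] > quality_threshold) & (~df["excluded"].astype(bool))]
    bad = kept[~kept["chaos_group"].isin(["high", "non_high"])]
    if len(bad):
        names = ", ".join(bad["class_name"].tolist())
        raise ClassMapError(f"classes without a valid group assignment: {names}")
    group = dict(zip(kept["class_name"], kept["chaos_group"]))

    def _flagged(col: str) -> frozenset[str]:
        if col not in df.columns:
            return frozenset()
        return frozenset(kept[kept[col].astype(bool)]["class_name"])

    return ChaosGroupMap(
        group=group,
        vehicle_like=_flagged("vehicle_like"),
        cry_like=_flagged("cry_like"),
        babble_like=_flagged("babble_like"),
    )


# -- prediction pruning ----------------------------------------------------


def filter_topk_confidence(
    preds: pd.DataFrame, k: int = TOP_K, min_confidence: float = MIN_CONFIDENCE
) -> pd.DataFrame:
    """Keep at most ``k`` predictions with confidence >= the floor, sorted descending."""
    if preds.empty:
        return preds.copy()
    out = preds[preds["confidence"] >= min_confidence]
    return out.sort_values("confidence", ascending=False, kind="mergesort").head(k)


def _max_rmse(frame_rmse) -> float:
    values = frame_rmse.values if isinstance(frame_rmse, FrameSeries) else np.asarray(frame_rmse)
    return float(np.max(values, initial=0.0))


def prune_cry_babble(
    preds: pd.DataFrame,
    segment_frame_rmse,
    stats: ParticipantStats,
    group_map: ChaosGroupMap,
) -> pd.DataFrame:
    """Resolve cry/babble co-predictions by participant-relative loudness.

    When both a cry-like and a babble-like class are predicted: if any
    frame RMSE exceeds 3x the participant's mean RMSE the segment is
    loud enough for crying (drop babble), otherwise drop cry.  With only
    one of the two present the predictions pass through unchanged.
    """
    if stats is None:
        raise ValueError("participant stats are required for cry/babble pruning")
    if preds.empty:
        return preds.copy()
    is_cry = preds["class_name"].isin(group_map.cry_like)
    is_babble = preds["class_name"].isin(group_map.babble_like)
    if not (is_cry.any() and is_babble.any()):
        return preds.copy()
    loud = _max_rmse(segment_frame_rmse) > CRY_RMSE_MULTIPLE * stats.mean_rmse
    return preds[~is_babble] if loud else preds[~is_cry]


def prune_whitenoise_vehicle(
    preds: pd.DataFrame,
    flatness,
    zc: int,
    group_map: ChaosGroupMap,
    drop_segment: bool = False,
) -> pd.DataFrame:
    """Drop vehicle-like predictions on steady-noise segments.

    The noise signature is: *all* spectral-flatness frames above 1e-4,
    or a zero-crossing count in [1000, 4000].  When the signature holds
    and a vehicle-like class is predicted, the vehicle-like
    prediction(s) are removed; with ``drop_segment=True`` the whole
    segment's prediction set is emptied instead (the alternative reading
    of the rule).
    """
    if preds.empty:
        return preds.copy()
    values = flatness.values if isinstance(flatness, FrameSeries) else np.asarray(flatness)
    noisy = bool(np.all(values > FLATNESS_THRESHOLD)) or (ZC_BAND[0] <= zc <= ZC_BAND[1])
    vehicle = preds["class_name"].isin(group_map.vehicle_like)
    if not (noisy and vehicle.any()):
        return preds.copy()
    if drop_segment:
        return preds.iloc[0:0].copy()
    return preds[~vehicle]


# -- candidate selection ---------------------------------------------------


@dataclass
class DetectorResult:
    segment_id: str
    is_candidate: bool
    trigger: str  # {"high_group_class", "loudness_override", "none"}
    pruned_predictions: pd.DataFrame = field(repr=False, default=None)


def detect_high_chaos(
    segment_preds: pd.DataFrame,
    frame_rmse,
    stats: ParticipantStats | None,
    group_map: ChaosGroupMap,
    segment_id: str = "",
) -> DetectorResult:
    """Candidate decision for one segment's *pruned* predictions.

    A segment is a candidate iff some surviving prediction maps to the
    high-chaos group, or any frame RMSE exceeds 7x the participant mean
    RMSE (the loudness override — applied even to an empty prediction
    set).  ``frame_rmse``/``stats`` may be None to run on prediction
    tables alone, in which case the override is unavailable.
    """
    has_high = (
        not segment_preds.empty
        and segment_preds["class_name"].map(group_map.is_high).any()
    )
    loud = (
        frame_rmse is not None
        and stats is not None
        and _max_rmse(frame_rmse) > LOUDNESS_RMSE_MULTIPLE * stats.mean_rmse
    )
    trigger = "high_group_class" if has_high else ("loudness_override" if loud else "none")
    return DetectorResult(segment_id, has_high or loud, trigger, segment_preds)


def run_detector(
    predictions: pd.DataFrame,
    group_map: ChaosGroupMap,
    frame_features: dict[str, dict] | None = None,
    stats: ParticipantStats | None = None,
    segment_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Full per-segment pipeline over a prediction table.

    ``predictions`` holds (segment_id, class_name, confidence) rows.
    ``frame_features`` optionally maps segment_id to
    ``{"rmse": FrameSeries, "flatness": FrameSeries, "zc": int}``;
    without it the acoustic pruning rules and the loudness override are
    skipped.  ``segment_ids`` extends the universe to segments with no
    predictions at all (still eligible for the override).

    Returns a DataFrame (segment_id, is_candidate, trigger).
    """
    ids = list(segment_ids) if segment_ids is not None else list(
        predictions["segment_id"].unique()
    )
    by_segment = dict(tuple(predictions.groupby("segment_id", sort=False)))
    empty = predictions.iloc[0:0]
    rows = []
    for sid in ids:
        preds = by_segment.get(sid, empty)
        preds = filter_topk_confidence(preds)
        rmse = flatness = None
        zc = -1
        if frame_features is not None and sid in frame_features:
            ff = frame_features[sid]
            rmse, flatness, zc = ff["rmse"], ff["flatness"], ff["zc"]
            if stats is not None:
                preds = prune_cry_babble(preds, rmse, stats, group_map)
            preds = prune_whitenoise_vehicle(preds, flatness, zc, group_map)
        res = detect_high_chaos(preds, rmse, stats, group_map, segment_id=sid)
        rows.append((sid, res.is_candidate, res.trigger))
    return pd.DataFrame(rows, columns=["segment_id", "is_candidate", "trigger"])


# -- efficiency evaluation -------------------------------------------------


@dataclass
class DetectorEfficiencyReport:
    """Detector efficiency on level-3 ground truth."""

    recall: float
    precision: float
    candidate_fraction: float
    enrichment: float
    candidate_high_rate: float
    random_high_rate: float
    n_candidates: int
    n_segments: int
    flags: tuple[str, ...] = ()


def evaluate_detector(
    results: pd.DataFrame,
    ground_truth: dict[str, int] | pd.Series,
    matched_random_sample: list[str] | None = None,
) -> DetectorEfficiencyReport:
    """Score detector output against level-3 ground truth.

    ``results`` is the (segment_id, is_candidate, ...) frame from
    :func:`run_detector`; ``ground_truth`` maps segment_id to chaos
    level.  ``matched_random_sample`` is a list of segment ids of the
    same size as the candidate set, drawn uniformly; enrichment is the
    ratio of the high-chaos rate among candidates to the rate in that
    sample.
    """
    truth = pd.Series(ground_truth)
    ids = results["segment_id"]
    labels = truth.loc[ids].to_numpy()
    flagged = results["is_candidate"].to_numpy(dtype=bool)
    is_high = labels == 3
    flags: list[str] = []

    n_high = int(is_high.sum())
    recall = float((flagged & is_high).sum() / n_high) if n_high else float("nan")
    if n_high == 0:
        flags.append("no_high_chaos_in_ground_truth")
    n_cand = int(flagged.sum())
    if n_cand:
        precision = float((flagged & is_high).sum() / n_cand)
        cand_rate = precision
    else:
        precision = cand_rate = float("nan")
        flags.append("empty_candidate_set")

    rand_rate = float("nan")
    enrichment = float("nan")
    if matched_random_sample is not None and len(matched_random_sample):
        rand_labels = truth.loc[list(matched_random_sample)].to_numpy()
        rand_rate = float((rand_labels == 3).mean())
        if rand_rate > 0 and n_cand:
            enrichment = cand_rate / rand_rate
        else:
            flags.append("enrichment_undefined")
    return DetectorEfficiencyReport(
        recall=recall,
        precision=precision,
        candidate_fraction=float(flagged.mean()),
        enrichment=enrichment,
        candidate_high_rate=cand_rate,
        random_high_rate=rand_rate,
        n_candidates=n_cand,
        n_segments=len(results),
        flags=tuple(flags),
    )
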