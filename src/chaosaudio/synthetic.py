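"""Synthetic labeled soundscapes and noisy sound-event prediction tables.

Real annotated daylong home recordings are membership-gated, so every
stage of the pipeline is exercised on synthetic material instead.  The
generator emulates the *structure* the pipeline assumes — 4-level chaos
labels on 5-s segments, per-segment (class, confidence) prediction
tables with realistic error modes — not acoustically realistic home
audio.

Chaos levels map onto synthesis recipes that mirror the annotation
scheme qualitatively:

* level 0 ("silence or absence of sounds") — near-silence, peak
  amplitude at most the silence threshold (0.01 full scale);
* level 1 ("soft daily or familiar sounds") — one smooth source: a low
  tone or steady white noise (a white-noise sleep machine is a level-1
  sound no matter how loud);
* level 2 ("slightly stimulating sounds") — two structured sources: a
  harmonic stack plus speech-like amplitude-modulated noise;
* level 3 ("highly stimulating, scary, or jarring sounds") — a dense
  mixture of 3+ overlapping sources always including an impulsive
  click train.

Two amplitude regimes exist.  In the default ("easy") regime loudness
grows with level.  In the *volume-confounded* regime levels 1-3 share a
single wide loudness distribution, so loud-but-calm (level-1 white
noise at high gain) and quiet-but-cacophonous (level-3 mixtures at low
gain) segments both occur and volume alone cannot separate the
non-silent classes — only spectral/temporal structure can.

All randomness flows from explicit integer seeds; identical
(spec, seed) pairs give bit-identical waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter

from . import classmap
from .audio import SAMPLE_RATE, AudioSegment, write_wav

SOURCE_KINDS = ("tone", "harmonic_stack", "am_speechlike", "white_noise", "impulse")

#: Peak amplitude at or below which a segment counts as level-0 silence.
SILENCE_THRESHOLD = 0.01


class SceneSpecError(ValueError):
    """Raised for internally inconsistent scene specifications."""


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one labeled synthetic scene.

    With ``volume_decoupled`` the mixed waveform is post-processed so
    that segment-level volume statistics (frame-RMSE mean/std, peak
    amplitude) are drawn from one class-independent distribution:
    envelope whitening, random waveshaping, a random slow AM envelope
    and RMS-targeted scaling.  ``amplitude_range`` is then interpreted
    as the target RMS range instead of the target peak range.
    """

    chaos_level: int
    duration_s: float = 5.0
    n_sources: int = 0
    amplitude_range: tuple[float, float] = (0.0, 0.0)
    source_kinds: tuple[str, ...] = ()
    seed: int = 0
    volume_decoupled: bool = False

    def __post_init__(self) -> None:
        if self.chaos_level not in (0, 1, 2, 3):
            raise SceneSpecError(f"chaos_level must be 0-3, got {self.chaos_level}")
        if self.duration_s <= 0:
            raise SceneSpecError("duration_s must be positive")
        lo, hi = self.amplitude_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise SceneSpecError(f"amplitude_range must lie in [0,1]: {self.amplitude_range}")
        unknown = set(self.source_kinds) - set(SOURCE_KINDS)
        if unknown:
            raise SceneSpecError(f"unknown source kinds: {sorted(unknown)}")
        if self.chaos_level == 0 and self.n_sources != 0:
            raise SceneSpecError("level 0 is silence; n_sources must be 0")
        if self.chaos_level == 3 and self.n_sources < 3 and "impulse" not in self.source_kinds:
            raise SceneSpecError(
                "level 3 requires >=3 sources or an impulsive source"
            )


@dataclass
class Scene:
    """A synthesized scene: waveform plus its construction metadata."""

    samples: np.ndarray
    chaos_level: int
    spec: SceneSpec
    kinds_used: tuple[str, ...]


# -- elementary sources ----------------------------------------------------


def _tone(n: int, rng: np.random.Generator, fmin=200.0, fmax=2000.0) -> np.ndarray:
    t = np.arange(n) / SAMPLE_RATE
    f = rng.uniform(fmin, fmax)
    return np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))


def _harmonic_stack(n: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / SAMPLE_RATE
    f0 = rng.uniform(150.0, 600.0)
    k = rng.integers(3, 7)  # 3-6 partials
    x = np.zeros(n)
    for p in range(1, k + 1):
        x += np.sin(2 * np.pi * p * f0 * t + rng.uniform(0, 2 * np.pi)) / p
    return x


def _am_speechlike(n: int, rng: np.random.Generator) -> np.ndarray:
    # band-limited noise (300-3000 Hz) with syllable-rate (3-8 Hz) AM
    noise = rng.standard_normal(n)
    b, a = butter(4, [300.0, 3000.0], btype="band", fs=SAMPLE_RATE)
    carrier = lfilter(b, a, noise)
    t = np.arange(n) / SAMPLE_RATE
    fm = rng.uniform(3.0, 8.0)
    env = 0.55 + 0.45 * np.sin(2 * np.pi * fm * t + rng.uniform(0, 2 * np.pi))
    return carrier * env


def _white_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.standard_normal(n)


def _impulse(n: int, rng: np.random.Generator) -> np.ndarray:
    # a sparse train of exponentially decaying broadband clicks
    x = np.zeros(n)
    n_clicks = int(rng.integers(2, 9))
    for _ in range(n_clicks):
        t0 = int(rng.integers(0, max(1, n - 1)))
        tau = rng.uniform(0.01, 0.04) * SAMPLE_RATE
        length = min(n - t0, int(6 * tau))
        if length <= 0:
            continue
        decay = np.exp(-np.arange(length) / tau)
        x[t0 : t0 + length] += decay * rng.standard_normal(length)
    return x


_SYNTH = {
    "tone": _tone,
    "harmonic_stack": _harmonic_stack,
    "am_speechlike": _am_speechlike,
    "white_noise": _white_noise,
    "impulse": _impulse,
}


def _decouple_volume(x: np.ndarray, rng: np.random.Generator, rms_range) -> np.ndarray:
    """Erase class information from segment-level volume statistics.

    Four class-independent randomizations: (1) whiten the ~50-ms local
    RMS envelope so temporal energy structure no longer tracks the
    source recipe; (2) sign-preserving waveshaping ``|x|**g`` with a
    random exponent, randomizing the crest factor (peak/RMS ratio);
    (3) a random slow AM envelope with random depth; (4) scaling to a
    target RMS drawn log-uniformly from ``rms_range``.  Spectral
    content remains class-specific; volume does not.
    """
    n = x.size
    win = 1102  # ~50 ms
    power = np.convolve(x**2, np.ones(win) / win, mode="same")
    env = np.sqrt(power)
    x = x / np.maximum(env, 1e-3 * max(env.max(), 1e-12))
    g = np.exp(rng.uniform(np.log(0.5), np.log(2.0)))
    x = np.sign(x) * np.abs(x) ** g
    t = np.arange(n) / SAMPLE_RATE
    depth = rng.uniform(0.0, 0.5)
    rate = rng.uniform(0.5, 4.0)
    x = x * (1.0 - depth + depth * np.sin(2 * np.pi * rate * t + rng.uniform(0, 2 * np.pi)))
    lo, hi = rms_range
    target = np.exp(rng.uniform(np.log(lo), np.log(hi)))
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = x * (target / rms)
    return np.clip(x, -1.0, 1.0)


def scene_spec_for_level(
    level: int, seed: int, confounded: bool = False, rng: np.random.Generator | None = None
) -> SceneSpec:
    """Default per-level recipe (the generator's study conditions).

    ``rng`` (if given) randomises within-level choices such as the
    level-1 source kind and the level-3 source count; the returned
    spec's own ``seed`` still fully determines the waveform.
    """
    rng = rng or np.random.default_rng(seed)
    if level == 0:
        return SceneSpec(0, 5.0, 0, (0.002, 0.008), (), seed)
    if confounded:
        amp = (0.02, 0.25)  # target RMS, shared by levels 1-3
    else:
        amp = {1: (0.05, 0.15), 2: (0.25, 0.45), 3: (0.55, 0.9)}[level]
    if level == 1:
        kind = "white_noise" if rng.random() < 0.5 else "tone"
        return SceneSpec(1, 5.0, 1, amp, (kind,), seed, confounded)
    if level == 2:
        return SceneSpec(
            2, 5.0, 2, amp, ("harmonic_stack", "am_speechlike"), seed, confounded
        )
    n_sources = int(rng.integers(4, 6))
    return SceneSpec(
        3, 5.0, n_sources, amp, ("impulse", "tone", "am_speechlike", "white_noise"),
        seed, confounded,
    )


def generate_scene(spec: SceneSpec) -> Scene:
    """Synthesize a labeled scene from its spec.

    The mixture is peak-normalised to a target drawn from
    ``spec.amplitude_range``, so peak amplitude is controlled exactly.
    Level-0 scenes are low-level noise clipped under the silence
    threshold.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * SAMPLE_RATE))
    if spec.chaos_level == 0:
        lo, hi = spec.amplitude_range
        target = min(rng.uniform(lo, hi) if hi > 0 else 0.0, SILENCE_THRESHOLD)
        x = rng.standard_normal(n)
        peak = np.max(np.abs(x))
        x = x * (target / peak) if peak > 0 else x
        return Scene(x, 0, spec, ())

    kinds: list[str] = []
    pool = list(spec.source_kinds) or ["tone"]
    if spec.chaos_level == 3 and "impulse" in pool:
        kinds.append("impulse")  # level 3 always carries the jarring source
    while len(kinds) < spec.n_sources:
        kinds.append(pool[len(kinds) % len(pool)] if len(kinds) < len(pool)
                     else str(rng.choice(pool)))
    x = np.zeros(n)
    for kind in kinds:
        src = _SYNTH[kind](n, rng)
        peak = np.max(np.abs(src))
        if peak > 0:
            src = src / peak
        x += src * rng.uniform(0.5, 1.0)
    if spec.volume_decoupled:
        x = _decouple_volume(x, rng, spec.amplitude_range)
    else:
        target = rng.uniform(*spec.amplitude_range)
        peak = np.max(np.abs(x))
        if peak > 0:
            x = x * (target / peak)
    return Scene(x, spec.chaos_level, spec, tuple(kinds))


# -- recordings ------------------------------------------------------------

SEGMENTS_PER_HOUR = 720


@dataclass
class SyntheticRecording:
    """A labeled synthetic recording, reproducible from its specs.

    Waveforms are synthesized on demand from the stored per-segment
    scene specs rather than held in memory (an hour of audio is ~300 MB
    as float64); ``segment(i)`` always returns the identical waveform
    for the same recording seed.
    """

    participant_id: str
    scene_specs: list[SceneSpec]
    labels: np.ndarray
    prevalence: tuple[float, float, float, float]
    confounded: bool = False
    _kinds_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_segments(self) -> int:
        return len(self.scene_specs)

    @property
    def segment_ids(self) -> list[str]:
        return [f"{self.participant_id}:{i}" for i in range(self.n_segments)]

    def segment(self, i: int) -> AudioSegment:
        scene = generate_scene(self.scene_specs[i])
        self._kinds_cache[i] = scene.kinds_used
        return AudioSegment(self.participant_id, i, scene.samples, float(i * 5))

    def iter_segments(self):
        for i in range(self.n_segments):
            yield self.segment(i)

    def segment_kinds(self, i: int) -> tuple[str, ...]:
        if i not in self._kinds_cache:
            self.segment(i)
        return self._kinds_cache[i]


def generate_recording(
    participant_id: str,
    hours: float,
    prevalence: tuple[float, float, float, float],
    seed: int,
    confounded: bool = False,
) -> SyntheticRecording:
    """Generate ``hours * 720`` labeled 5-s segments.

    ``prevalence`` gives the class probabilities for levels 0-3 and must
    sum to 1; labels are drawn i.i.d., so empirical fractions sit within
    binomial sampling error of the request.
    """
    prev = np.asarray(prevalence, dtype=float)
    if prev.size != 4 or np.any(prev < 0) or abs(prev.sum() - 1.0) > 1e-9:
        raise ValueError("prevalence must be 4 non-negative values summing to 1")
    if hours <= 0:
        raise ValueError("hours must be positive")
    n = int(round(hours * SEGMENTS_PER_HOUR))
    rng = np.random.default_rng(seed)
    labels = rng.choice(4, size=n, p=prev)
    seg_seeds = rng.integers(0, 2**31 - 1, size=n)
    specs = [
        scene_spec_for_level(int(labels[i]), int(seg_seeds[i]), confounded, rng)
        for i in range(n)
    ]
    return SyntheticRecording(participant_id, specs, labels, tuple(prev), confounded)


def labels_table(recording: SyntheticRecording) -> pd.DataFrame:
    """Labels as (participant_id, segment_index, chaos_level)."""
    return pd.DataFrame(
        {
            "participant_id": recording.participant_id,
            "segment_index": np.arange(recording.n_segments),
            "chaos_level": recording.labels.astype(int),
        }
    )


# -- synthetic prediction tables -------------------------------------------


@dataclass(frozen=True)
class PredictionNoiseSpec:
    """Error model for synthetic sound-event prediction tables.

    ``miss_rate`` — probability a true level-3 segment carries no
    high-group class; ``false_alarm_rate`` — probability a level<3
    segment carries one; the confusion rates emulate the documented
    error modes of the external classifier (cry mistaken for babble and
    vice versa; steady white noise mistaken for vehicles).
    """

    miss_rate: float = 0.35
    false_alarm_rate: float = 0.037
    cry_babble_confusion: float = 0.2
    whitenoise_vehicle_confusion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("miss_rate", "false_alarm_rate", "cry_babble_confusion",
                     "whitenoise_vehicle_confusion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


_PLAIN_HIGH = tuple(
    c for c in classmap.HIGH_CLASS_NAMES
    if c != classmap.CRY_CLASS and c not in classmap.VEHICLE_CLASSES
)
_FILLER = tuple(
    c for c in classmap.NON_HIGH_CLASS_NAMES
    if c not in (classmap.BABBLE_CLASS, classmap.WHITE_NOISE_CLASS)
)


def generate_prediction_table(
    recording: SyntheticRecording, noise: PredictionNoiseSpec
) -> pd.DataFrame:
    """Per-segment (class, confidence) records with controlled error modes.

    Each segment gets 1-15 records.  True level-3 segments carry a
    high-group class (confidence in [0.4, 0.95]) with probability
    ``1 - miss_rate``; lower levels carry one with probability
    ``false_alarm_rate``.  Filler non-high classes have confidences in
    [1e-5, 0.3] — some below the detector's 1e-4 floor by design.
    White-noise level-1 segments additionally pick up a vehicle-like
    class with probability ``whitenoise_vehicle_confusion``; cry
    predictions pick up a babble co-prediction (and vice versa) with
    probability ``cry_babble_confusion``.
    """
    rows: list[tuple[int, str, str, float]] = []
    for i in range(recording.n_segments):
        rng = np.random.default_rng([noise.seed, recording.scene_specs[i].seed])
        level = int(recording.labels[i])
        spec_kinds = recording.scene_specs[i].source_kinds
        preds: list[tuple[str, float]] = []

        if level == 3:
            if rng.random() >= noise.miss_rate:
                if rng.random() < 0.25:
                    cls = classmap.CRY_CLASS
                    if rng.random() < noise.cry_babble_confusion:
                        preds.append((classmap.BABBLE_CLASS, rng.uniform(0.1, 0.4)))
                else:
                    cls = str(rng.choice(_PLAIN_HIGH))
                preds.append((cls, rng.uniform(0.4, 0.95)))
        else:
            if rng.random() < noise.false_alarm_rate:
                preds.append((str(rng.choice(_PLAIN_HIGH)), rng.uniform(0.4, 0.95)))
            if "white_noise" in spec_kinds:
                preds.append((classmap.WHITE_NOISE_CLASS, rng.uniform(0.3, 0.8)))
                if rng.random() < noise.whitenoise_vehicle_confusion:
                    preds.append(
                        (str(rng.choice(classmap.VEHICLE_CLASSES)), rng.uniform(0.4, 0.9))
                    )
            if level in (1, 2) and rng.random() < 0.15:
                preds.append((classmap.BABBLE_CLASS, rng.uniform(0.2, 0.6)))
                if rng.random() < noise.cry_babble_confusion:
                    preds.append((classmap.CRY_CLASS, rng.uniform(0.2, 0.6)))

        n_filler = int(rng.integers(1, 10 - min(len(preds), 5)))
        for cls in rng.choice(_FILLER, size=n_filler, replace=False):
            preds.append((str(cls), float(10 ** rng.uniform(-5, np.log10(0.3)))))
        preds = preds[:15]
        sid = f"{recording.participant_id}:{i}"
        rows.extend((i, sid, c, float(conf)) for c, conf in preds)
    return pd.DataFrame(
        rows, columns=["segment_index", "segment_id", "class_name", "confidence"]
    )


# -- disk interchange ------------------------------------------------------


def write_recording(recording: SyntheticRecording, out_dir: str | Path) -> dict[str, Path]:
    """Write WAV audio, a labels CSV and return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wav_path = out / f"{recording.participant_id}.wav"
    audio = np.concatenate([recording.segment(i).samples for i in range(recording.n_segments)])
    write_wav(wav_path, audio)
    labels_path = out / f"{recording.participant_id}_labels.csv"
    labels_table(recording).to_csv(labels_path, index=False)
    return {"wav": wav_path, "labels": labels_path}


def write_predictions_jsonl(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_json(path, orient="records", lines=True)
    return path
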