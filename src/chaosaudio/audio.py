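"""Audio I/O and segmentation.

Daylong child-worn recordings arrive as WAV files of arbitrary rate and
channel count.  Everything downstream of this module works on a single
canonical representation: mono float waveforms in [-1, 1] sampled at
22,050 Hz, cut into non-overlapping, contiguous 5-second segments of
exactly 110,250 samples.  A trailing remainder shorter than 5 s is
dropped, so a recording of duration ``d`` seconds yields ``floor(d / 5)``
segments (one hour -> 720 segments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

#: Canonical sampling rate in Hz.
SAMPLE_RATE = 22_050

#: Segment duration in seconds.
SEGMENT_SECONDS = 5

#: Samples per canonical segment (5 s at 22,050 Hz).
SEGMENT_SAMPLES = SAMPLE_RATE * SEGMENT_SECONDS


class AudioValidationError(ValueError):
    """Raised when audio input violates the canonical contract."""


@dataclass
class Recording:
    """A mono waveform at the canonical sampling rate.

    Attributes
    ----------
    participant_id:
        Identifier of the participant who wore the recorder.
    samples:
        1-D float array, amplitudes in [-1, 1].
    sample_rate:
        Always 22,050 Hz after normalization.
    """

    participant_id: str
    samples: np.ndarray
    sample_rate: int = SAMPLE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).reshape(-1)
        if self.samples.size == 0:
            raise AudioValidationError("recording has zero-length audio")
        if not np.all(np.isfinite(self.samples)):
            raise AudioValidationError("recording contains non-finite samples")
        if self.sample_rate != SAMPLE_RATE:
            raise AudioValidationError(
                f"recording must be at {SAMPLE_RATE} Hz, got {self.sample_rate}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def n_segments(self) -> int:
        return int(math.floor(self.duration_s / SEGMENT_SECONDS))


@dataclass
class AudioSegment:
    """One 5-second analysis unit: exactly 110,250 samples at 22,050 Hz."""

    participant_id: str
    segment_index: int
    samples: np.ndarray
    start_time_s: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).reshape(-1)
        if self.samples.size != SEGMENT_SAMPLES:
            raise AudioValidationError(
                f"segment must have {SEGMENT_SAMPLES} samples, got {self.samples.size}"
            )

    @property
    def segment_id(self) -> str:
        return f"{self.participant_id}:{self.segment_index}"


def _to_float(samples: np.ndarray) -> np.ndarray:
    """Scale integer PCM to floats in [-1, 1]; pass floats through."""
    if np.issubdtype(samples.dtype, np.floating):
        return samples.astype(np.float64)
    info = np.iinfo(samples.dtype)
    if info.min < 0:  # signed PCM (16/32 bit)
        return samples.astype(np.float64) / float(-info.min)
    # unsigned 8-bit WAV is offset binary
    half = (info.max + 1) / 2
    return (samples.astype(np.float64) - half) / half


def load_recording(path: str | Path, participant_id: str) -> Recording:
    """Read a WAV file, mix down to mono and resample to 22,050 Hz.

    Parameters
    ----------
    path:
        WAV file of any sample rate / channel count.
    participant_id:
        Identifier attached to the returned :class:`Recording`.

    Raises
    ------
    IOError
        If the file cannot be read as WAV (message names the path).
    AudioValidationError
        If the decoded audio is empty.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / non-WAV payloads
        raise IOError(f"could not read WAV file {path}: {exc}") from exc
    data = np.atleast_1d(np.asarray(data))
    if data.size == 0:
        raise AudioValidationError(f"zero-length audio in {path}")
    samples = _to_float(data)
    if samples.ndim == 2:  # (n, channels) -> mono mixdown
        samples = samples.mean(axis=1)
    if rate != SAMPLE_RATE:
        g = math.gcd(SAMPLE_RATE, int(rate))
        samples = resample_poly(samples, SAMPLE_RATE // g, int(rate) // g)
    samples = np.clip(samples, -1.0, 1.0)
    return Recording(participant_id=participant_id, samples=samples)


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int = SAMPLE_RATE) -> None:
    """Write float samples in [-1, 1] as 16-bit PCM WAV."""
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(Path(path), sample_rate, pcm)


def segment_recording(recording: Recording) -> list[AudioSegment]:
    """Cut a recording into non-overlapping contiguous 5-s segments.

    Returns ``floor(duration / 5)`` segments with consecutive 0-based
    indices; a trailing remainder shorter than 5 s is dropped.  Durations
    under 5 s yield an empty list.
    """
    n = recording.n_segments
    out = []
    for i in range(n):
        lo = i * SEGMENT_SAMPLES
        out.append(
            AudioSegment(
                participant_id=recording.participant_id,
                segment_index=i,
                samples=recording.samples[lo : lo + SEGMENT_SAMPLES],
                start_time_s=float(i * SEGMENT_SECONDS),
            )
        )
    return out


def n_segments_for_duration(duration_s: float) -> int:
    """Segment-count law: ``floor(duration_s / 5)``."""
    return int(math.floor(duration_s / SEGMENT_SECONDS))


def segment_manifest(segments: list[AudioSegment], source_path: str = "") -> pd.DataFrame:
    """Tabulate segments as (participant_id, segment_index, start_time_s, source_path)."""
    return pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in segments],
            "segment_index": [s.segment_index for s in segments],
            "start_time_s": [s.start_time_s for s in segments],
            "source_path": source_path,
        }
    )
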