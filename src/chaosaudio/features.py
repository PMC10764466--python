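"""Framewise and segment-level acoustic features.

All framewise features share one framing convention: a sliding window of
512 samples with a hop of 256 samples, *centered* (the signal is padded
by half a window on each side, so frame ``t`` is centered on sample
``t * hop``).  Under this convention a canonical 5-s segment (110,250
samples at 22,050 Hz) yields ``1 + floor(110250 / 256) = 431`` frames.
Centered framing is load-bearing: the uncentered convention would give
429 frames for the same segment.

Three feature surfaces are exposed:

* the detector's inputs — per-frame RMSE and spectral flatness series,
  the segment-level zero-crossing count, and the participant's grand
  mean RMSE used to normalise loudness (3x / 7x rules);
* ``extract_features3`` / ``extract_features53`` — the volume baseline
  (mean/std RMSE + peak amplitude) and the 53-dimensional classical
  feature vector (mean+std of 20 MFCCs, zero-crossing rate, spectral
  flatness/rolloff/centroid/bandwidth, RMSE, plus peak amplitude);
* ``logmel_patches`` — 2-s, 96-band log-mel spectrogram patches that
  feed the CNN (window 40 ms, 50% overlap; sub-2-s tails are replicated
  to full length).

MFCC filter-bank parameters, the log floor and the spectral-statistic
conventions are not uniquely determined by the framing contract; the
choices here are fixed in :class:`FramingConfig` / module constants and
documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft

from .audio import SAMPLE_RATE, AudioSegment, AudioValidationError, Recording

# -- framing ---------------------------------------------------------------


@dataclass(frozen=True)
class FramingConfig:
    """Sliding-window convention shared by all framewise features."""

    window_samples: int = 512
    hop_samples: int = 256
    centered: bool = True
    sample_rate: int = SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.hop_samples > self.window_samples:
            raise ValueError("hop must not exceed window")

    def n_frames(self, n_samples: int) -> int:
        """Frame-count law for centered framing: ``1 + floor(n / hop)``."""
        if self.centered:
            return 1 + n_samples // self.hop_samples
        return 1 + (n_samples - self.window_samples) // self.hop_samples


DEFAULT_FRAMING = FramingConfig()

#: Log floor applied before any spectral logarithm (mel energies, flatness).
LOG_FLOOR = 1e-10

#: Mel filter-bank settings for MFCCs (paper-silent; fixed here).
N_MELS_MFCC = 40
N_MFCC = 20

#: Spectral-rolloff energy fraction.
ROLLOFF_FRACTION = 0.85

# log-mel patch settings for the CNN front end
PATCH_SECONDS = 2
MEL_BANDS = 96
MEL_WINDOW = 882  # 40 ms at 22,050 Hz
MEL_HOP = 441  # 50% overlap


@dataclass
class FrameSeries:
    """A named per-frame feature series under a fixed framing."""

    name: str
    values: np.ndarray
    framing: FramingConfig = field(default_factory=FramingConfig)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ParticipantStats:
    """Participant-level loudness normaliser: grand mean frame RMSE."""

    participant_id: str
    mean_rmse: float


def _samples(segment) -> np.ndarray:
    if isinstance(segment, (AudioSegment, Recording)):
        return segment.samples
    return np.asarray(segment, dtype=np.float64).reshape(-1)


def frame_signal(x: np.ndarray, framing: FramingConfig = DEFAULT_FRAMING) -> np.ndarray:
    """Slice a signal into overlapping frames, shape (n_frames, window).

    With ``centered=True`` the signal is zero-padded by ``window // 2`` on
    both sides and frame ``t`` covers padded samples
    ``[t*hop, t*hop + window)``, i.e. is centered on original sample
    ``t*hop``.
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    w, h = framing.window_samples, framing.hop_samples
    if framing.centered:
        x = np.pad(x, w // 2)
    n_frames = 1 + (x.size - w) // h
    view = np.lib.stride_tricks.sliding_window_view(x, w)[::h]
    return view[:n_frames]


# -- framewise series ------------------------------------------------------


def frame_rmse(segment, framing: FramingConfig = DEFAULT_FRAMING) -> FrameSeries:
    """Root-mean-square energy per frame (431 values for a 5-s segment)."""
    frames = frame_signal(_samples(segment), framing)
    values = np.sqrt(np.mean(frames**2, axis=1))
    return FrameSeries("rmse", values, framing)


def _power_spectra(segment, framing: FramingConfig) -> np.ndarray:
    """Hann-windowed one-sided power spectra, shape (n_frames, n_fft//2+1)."""
    frames = frame_signal(_samples(segment), framing)
    window = np.hanning(framing.window_samples)
    spec = rfft(frames * window, axis=1)
    return np.abs(spec) ** 2


def spectral_flatness_series(
    segment, framing: FramingConfig = DEFAULT_FRAMING
) -> FrameSeries:
    """Per-frame spectral flatness: geometric / arithmetic mean of power.

    Near 1 for white noise, near 0 for tonal signals.  Each frame's
    power spectrum is floored at 1e-10 of its own peak before the
    geometric mean, so the statistic is scale-invariant and a line
    spectrum reads as tonal (well under the detector's 1e-4 noise
    threshold) at any amplitude.  An all-zero frame has every bin at
    the floor, hence flatness exactly 1 (silence is "flat") — relevant
    because the detector's white-noise signature is *all* frame values
    above 1e-4.
    """
    power = _power_spectra(segment, framing)
    floor = np.maximum(LOG_FLOOR * power.max(axis=1, keepdims=True), 1e-30)
    power = np.maximum(power, floor)
    gmean = np.exp(np.mean(np.log(power), axis=1))
    amean = np.mean(power, axis=1)
    return FrameSeries("spectral_flatness", gmean / amean, framing)


def peak_amplitude(segment) -> float:
    """Maximum absolute amplitude over the whole segment."""
    return float(np.max(np.abs(_samples(segment)), initial=0.0))


def zero_crossings(segment) -> int:
    """Segment-level count of sign transitions over the full 5 s.

    A transition is positive->negative or negative->positive; runs of
    exact zeros between opposite signs count as a single crossing
    (positive -> zero -> negative is one crossing), and zeros flanked by
    equal signs count none.
    """
    x = _samples(segment)
    signs = np.sign(x)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(signs[1:] != signs[:-1]))


def frame_zero_crossing_rate(
    segment, framing: FramingConfig = DEFAULT_FRAMING
) -> FrameSeries:
    """Per-frame zero-crossing rate: sign changes / (window - 1).

    Uses the same zero-handling rule as :func:`zero_crossings`, applied
    within each frame.
    """
    frames = frame_signal(_samples(segment), framing)
    w = framing.window_samples
    values = np.empty(frames.shape[0])
    for i, fr in enumerate(frames):
        s = np.sign(fr)
        s = s[s != 0]
        values[i] = 0.0 if s.size < 2 else np.count_nonzero(s[1:] != s[:-1]) / (w - 1)
    return FrameSeries("zero_crossing_rate", values, framing)


def _fft_bin_freqs(framing: FramingConfig) -> np.ndarray:
    n_fft = framing.window_samples
    return np.fft.rfftfreq(n_fft, d=1.0 / framing.sample_rate)


def spectral_centroid_series(segment, framing: FramingConfig = DEFAULT_FRAMING) -> FrameSeries:
    """Per-frame magnitude-weighted mean frequency (Hz); 0 for silent frames."""
    mag = np.sqrt(_power_spectra(segment, framing))
    freqs = _fft_bin_freqs(framing)
    total = mag.sum(axis=1)
    safe = np.where(total > 0, total, 1.0)
    centroid = (mag * freqs).sum(axis=1) / safe
    centroid[total == 0] = 0.0
    return FrameSeries("spectral_centroid", centroid, framing)


def spectral_bandwidth_series(segment, framing: FramingConfig = DEFAULT_FRAMING) -> FrameSeries:
    """Per-frame magnitude-weighted std of frequency around the centroid (Hz)."""
    mag = np.sqrt(_power_spectra(segment, framing))
    freqs = _fft_bin_freqs(framing)
    total = mag.sum(axis=1)
    safe = np.where(total > 0, total, 1.0)
    centroid = (mag * freqs).sum(axis=1) / safe
    dev2 = (freqs[None, :] - centroid[:, None]) ** 2
    bw = np.sqrt((mag * dev2).sum(axis=1) / safe)
    bw[total == 0] = 0.0
    return FrameSeries("spectral_bandwidth", bw, framing)


def spectral_rolloff_series(
    segment,
    framing: FramingConfig = DEFAULT_FRAMING,
    fraction: float = ROLLOFF_FRACTION,
) -> FrameSeries:
    """Per-frame frequency below which ``fraction`` of spectral energy lies."""
    power = _power_spectra(segment, framing)
    freqs = _fft_bin_freqs(framing)
    csum = np.cumsum(power, axis=1)
    total = csum[:, -1]
    values = np.empty(power.shape[0])
    for i in range(power.shape[0]):
        if total[i] <= 0:
            values[i] = 0.0
        else:
            idx = int(np.searchsorted(csum[i], fraction * total[i]))
            values[i] = freqs[min(idx, freqs.size - 1)]
    return FrameSeries("spectral_rolloff", values, framing)


# -- mel / MFCC ------------------------------------------------------------


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int,
    n_fft: int,
    sample_rate: int = SAMPLE_RATE,
    fmin: float = 0.0,
    fmax: float | None = None,
) -> np.ndarray:
    """Triangular mel filter bank, shape (n_mels, n_fft//2 + 1).

    HTK-style mel scale, unit-peak triangles spanning [fmin, fmax]
    (fmax defaults to Nyquist).
    """
    if fmax is None:
        fmax = sample_rate / 2.0
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, bin_freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bin_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc_series(
    segment,
    framing: FramingConfig = DEFAULT_FRAMING,
    n_mfcc: int = N_MFCC,
    n_mels: int = N_MELS_MFCC,
) -> np.ndarray:
    """Per-frame MFCCs, shape (n_frames, n_mfcc).

    Power spectrum -> mel energies (40 triangular filters, 0 Hz to
    Nyquist) -> natural log with floor -> orthonormal DCT-II, keeping the
    first 20 coefficients.
    """
    power = _power_spectra(segment, framing)
    fb = mel_filterbank(n_mels, framing.window_samples, framing.sample_rate)
    mel_energy = power @ fb.T
    log_mel = np.log(np.maximum(mel_energy, LOG_FLOOR))
    coeffs = dct(log_mel, type=2, axis=1, norm="ortho")
    return coeffs[:, :n_mfcc]


# -- segment-level feature vectors ----------------------------------------

#: Column order of the 53-feature vector: 26 framewise means, the same 26
#: standard deviations, then peak amplitude.
_BASE26 = (
    [f"mfcc{i + 1}" for i in range(N_MFCC)]
    + [
        "zero_crossing_rate",
        "spectral_flatness",
        "spectral_rolloff",
        "spectral_centroid",
        "spectral_bandwidth",
        "rmse",
    ]
)
FEATURE53_NAMES: tuple[str, ...] = tuple(
    [f"{n}_mean" for n in _BASE26] + [f"{n}_std" for n in _BASE26] + ["peak_amplitude"]
)

FEATURE3_NAMES: tuple[str, ...] = ("rmse_mean", "rmse_std", "peak_amplitude")


def extract_features53(
    segment, framing: FramingConfig = DEFAULT_FRAMING
) -> np.ndarray:
    """The 53-dimensional classical acoustic feature vector (26*2 + 1).

    Mean and standard deviation across frames of: 20 MFCCs,
    zero-crossing rate, spectral flatness, rolloff, centroid and
    bandwidth, and RMSE — plus the segment peak amplitude.  Ordering
    follows :data:`FEATURE53_NAMES`.
    """
    series = np.column_stack(
        [
            mfcc_series(segment, framing),
            frame_zero_crossing_rate(segment, framing).values,
            spectral_flatness_series(segment, framing).values,
            spectral_rolloff_series(segment, framing).values,
            spectral_centroid_series(segment, framing).values,
            spectral_bandwidth_series(segment, framing).values,
            frame_rmse(segment, framing).values,
        ]
    )
    out = np.concatenate(
        [series.mean(axis=0), series.std(axis=0), [peak_amplitude(segment)]]
    )
    assert out.size == 53
    return out


def extract_features3(segment, framing: FramingConfig = DEFAULT_FRAMING) -> np.ndarray:
    """Volume-only baseline features: (mean RMSE, std RMSE, peak amplitude)."""
    r = frame_rmse(segment, framing).values
    return np.array([r.mean(), r.std(), peak_amplitude(segment)])


# -- log-mel patches for the CNN ------------------------------------------


@dataclass
class MelPatchSet:
    """2-s log-mel patches derived from one segment (96 bands each)."""

    segment_id: str
    patches: list[np.ndarray]
    patch_length_s: float = float(PATCH_SECONDS)

    def as_array(self) -> np.ndarray:
        return np.stack(self.patches)


def _logmel(x: np.ndarray) -> np.ndarray:
    framing = FramingConfig(
        window_samples=MEL_WINDOW, hop_samples=MEL_HOP, centered=True
    )
    power = _power_spectra(x, framing)
    fb = mel_filterbank(MEL_BANDS, MEL_WINDOW)
    mel = power @ fb.T
    return np.log(np.maximum(mel, LOG_FLOOR)).T  # (bands, frames)


def logmel_patches(segment) -> MelPatchSet:
    """Chunk a segment into 2-s patches and log-mel transform each.

    A 5-s segment yields three patches (2 s, 2 s, and a 1-s tail
    replicated to 2 s).  Each patch is a (96, 101) log-mel matrix:
    40-ms window (882 samples), 50% overlap, centered framing.
    """
    x = _samples(segment)
    patch_len = PATCH_SECONDS * SAMPLE_RATE
    sid = segment.segment_id if isinstance(segment, AudioSegment) else "segment"
    patches = []
    for lo in range(0, x.size, patch_len):
        chunk = x[lo : lo + patch_len]
        if chunk.size == 0:
            break
        if chunk.size < patch_len:  # replicate short tails to full length
            reps = int(np.ceil(patch_len / chunk.size))
            chunk = np.tile(chunk, reps)[:patch_len]
        patches.append(_logmel(chunk))
    return MelPatchSet(segment_id=sid, patches=patches)


def participant_mean_rmse(recording: Recording) -> ParticipantStats:
    """Grand mean of frame RMSE over all 5-s segments of a recording.

    This is the participant-level normaliser behind the 3x (cry/babble)
    and 7x (loudness override) rules.
    """
    from .audio import segment_recording

    segments = segment_recording(recording)
    if not segments:
        raise AudioValidationError(
            "recording shorter than one 5-s segment; cannot compute participant stats"
        )
    total, count = 0.0, 0
    for seg in segments:
        v = frame_rmse(seg).values
        total += v.sum()
        count += v.size
    return ParticipantStats(recording.participant_id, total / count)
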