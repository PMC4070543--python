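"""Narrow-filterbank MFCC front end for sustained-vowel recordings.

Each utterance is reduced to a single 120-dimensional descriptor: 40 static
cepstral coefficients from a 40-filter mel filterbank (narrower filters than
the usual 13-filter ASR bank, so less spectral smoothing), plus 40 delta and
40 delta-delta regression coefficients computed over the utterance's frame
sequence and sampled at the central frame.  Sustained vowels are close to
stationary, so the choice of frame carries little information; the deltas of
a steady vowel are near zero and mostly encode recording stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.fft
from scipy.io import wavfile

VOWELS: tuple[str, ...] = ("a", "e", "ə", "i", "o", "u")

__all__ = [
    "VOWELS",
    "AudioSignal",
    "MFCCConfig",
    "MelFilterbank",
    "FeatureVector",
    "hz_to_mel",
    "mel_to_hz",
    "build_mel_filterbank",
    "frame_signal",
    "static_mfcc",
    "delta_coefficients",
    "extract_features",
    "read_wav",
    "write_wav",
    "features_to_frame",
    "save_feature_table",
    "load_feature_table",
]


@dataclass(frozen=True)
class AudioSignal:
    """A mono waveform with amplitudes nominally in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if int(self.sample_rate) <= 0:
            raise ValueError("sample_rate must be a positive integer")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class MFCCConfig:
    """Front-end parameters.

    Defaults: 55 ms frames with 50% overlap, a 40-filter mel bank spanning
    0..Nyquist, 40 static coefficients (full-rank DCT), +-2-frame regression
    deltas, 0.97 pre-emphasis and a Hamming window.
    """

    frame_length_ms: float = 55.0
    hop_length_ms: float = 27.5
    n_filters: int = 40
    n_static: int = 40
    delta_window: int = 2
    fmin: float = 0.0
    fmax: float | None = None  # None means Nyquist
    log_floor: float = 1e-10
    preemphasis: float = 0.97

    def __post_init__(self) -> None:
        if self.frame_length_ms <= 0 or self.hop_length_ms <= 0:
            raise ValueError("frame and hop lengths must be positive")
        if self.n_static > self.n_filters:
            raise ValueError("n_static must not exceed n_filters")
        if not 0 <= self.preemphasis < 1:
            raise ValueError("preemphasis must lie in [0, 1)")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        if self.delta_window < 1:
            raise ValueError("delta_window must be >= 1")

    def frame_length(self, sample_rate: int) -> int:
        return int(round(self.frame_length_ms * sample_rate / 1000.0))

    def hop_length(self, sample_rate: int) -> int:
        return int(round(self.hop_length_ms * sample_rate / 1000.0))

    def resolve_fmax(self, sample_rate: int) -> float:
        fmax = sample_rate / 2.0 if self.fmax is None else float(self.fmax)
        if not self.fmin < fmax <= sample_rate / 2.0:
            raise ValueError("need fmin < fmax <= Nyquist")
        return fmax


@dataclass(frozen=True)
class MelFilterbank:
    """Triangular filters, one row per filter over the rFFT bins."""

    weights: np.ndarray  # (n_filters, n_fft // 2 + 1)
    center_frequencies: np.ndarray  # Hz, strictly increasing

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class FeatureVector:
    """One utterance's [static, delta, delta-delta] descriptor."""

    values: np.ndarray
    vowel_label: str = "unknown"
    age_label: int | None = None
    speaker_id: str = "unknown"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", values)


def hz_to_mel(frequency):
    """HTK-style mel scale: 2595 * log10(1 + f / 700)."""
    frequency = np.asarray(frequency, dtype=np.float64)
    if np.any(frequency < 0):
        raise ValueError("frequency must be non-negative")
    return 2595.0 * np.log10(1.0 + frequency / 700.0)


def mel_to_hz(mel):
    mel = np.asarray(mel, dtype=np.float64)
    return 700.0 * (10.0 ** (mel / 2595.0) - 1.0)


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def build_mel_filterbank(
    config: MFCCConfig, sample_rate: int, n_fft: int
) -> MelFilterbank:
    """Construct triangular filters equally spaced on the mel scale.

    Adjacent triangles overlap at their neighbours' centers; the left and
    right edges of the bank sit at ``fmin`` and ``fmax``.  Raises if ``n_fft``
    is too small to resolve distinct center bins for adjacent filters.
    """
    fmax = config.resolve_fmax(sample_rate)
    mel_points = np.linspace(
        hz_to_mel(config.fmin), hz_to_mel(fmax), config.n_filters + 2
    )
    hz_points = mel_to_hz(mel_points)
    centers = hz_points[1:-1]

    center_bins = np.round(centers * n_fft / sample_rate).astype(int)
    if np.unique(center_bins).size != centers.size:
        raise ValueError(
            f"n_fft={n_fft} cannot resolve {config.n_filters} distinct mel "
            "filter centers; increase n_fft or reduce n_filters"
        )

    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    weights = np.zeros((config.n_filters, bin_freqs.size))
    for i in range(config.n_filters):
        left, center, right = hz_points[i], hz_points[i + 1], hz_points[i + 2]
        rising = (bin_freqs - left) / (center - left)
        falling = (right - bin_freqs) / (right - center)
        weights[i] = np.maximum(0.0, np.minimum(rising, falling))

    return MelFilterbank(weights=weights, center_frequencies=centers)


def frame_signal(signal: AudioSignal, config: MFCCConfig) -> np.ndarray:
    """Slice the waveform into pre-emphasized, Hamming-windowed frames.

    Returns an (n_frames, frame_length) array; the trailing partial frame is
    dropped.  Raises if the signal is shorter than one frame.
    """
    frame_len = config.frame_length(signal.sample_rate)
    hop = config.hop_length(signal.sample_rate)
    x = signal.samples
    if x.size < frame_len:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one "
            f"{frame_len}-sample frame"
        )
    n_frames = (x.size - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    # pre-emphasis within each frame: e[0] = f[0], e[t] = f[t] - a * f[t-1]
    emphasized = frames.copy()
    emphasized[:, 1:] -= config.preemphasis * frames[:, :-1]
    return emphasized * np.hamming(frame_len)


def static_mfcc(
    frame: np.ndarray,
    filterbank: MelFilterbank,
    n_static: int,
    log_floor: float,
) -> np.ndarray:
    """Static cepstra of one windowed frame.

    Power spectrum -> filterbank energies -> floored log -> orthonormal
    DCT-II, keeping the first ``n_static`` coefficients (0th included).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    n_fft = 2 * (filterbank.weights.shape[1] - 1)
    power = np.abs(np.fft.rfft(frame, n_fft)) ** 2
    energies = filterbank.weights @ power
    log_energies = np.log(np.maximum(energies, log_floor))
    cepstra = scipy.fft.dct(log_energies, type=2, norm="ortho")
    return cepstra[:n_static]


def delta_coefficients(static_sequence: np.ndarray, window: int = 2) -> np.ndarray:
    """First-order regression deltas over a (n_frames, n_coeff) sequence.

    Edges are padded by repeating the boundary frames, so a single-frame
    (or any constant) sequence has identically zero deltas.
    """
    seq = np.atleast_2d(np.asarray(static_sequence, dtype=np.float64))
    padded = np.pad(seq, ((window, window), (0, 0)), mode="edge")
    denom = 2.0 * sum(k * k for k in range(1, window + 1))
    deltas = np.zeros_like(seq)
    for k in range(1, window + 1):
        deltas += k * (padded[window + k : padded.shape[0] - window + k]
                       - padded[window - k : padded.shape[0] - window - k])
    return deltas / denom


def extract_features(
    signal: AudioSignal,
    config: MFCCConfig | None = None,
    *,
    vowel_label: str = "unknown",
    age_label: int | None = None,
    speaker_id: str = "unknown",
) -> FeatureVector:
    """Compute the utterance's single-frame 120-dimensional descriptor.

    All frames are processed so the delta regression sees real temporal
    context; the central frame's [static, delta, delta-delta] triplet is the
    utterance's feature vector.
    """
    config = config or MFCCConfig()
    frames = frame_signal(signal, config)
    n_fft = _next_pow2(frames.shape[1])
    bank = build_mel_filterbank(config, signal.sample_rate, n_fft)
    static = np.stack(
        [static_mfcc(f, bank, config.n_static, config.log_floor) for f in frames]
    )
    delta = delta_coefficients(static, config.delta_window)
    delta2 = delta_coefficients(delta, config.delta_window)
    mid = frames.shape[0] // 2
    values = np.concatenate([static[mid], delta[mid], delta2[mid]])
    return FeatureVector(
        values=values,
        vowel_label=vowel_label,
        age_label=age_label,
        speaker_id=speaker_id,
    )


# ---------------------------------------------------------------------------
# WAV and feature-table I/O


def read_wav(path: str | Path) -> AudioSignal:
    """Read a mono PCM WAV into a float signal scaled to [-1, 1]."""
    sample_rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioSignal(samples=data, sample_rate=int(sample_rate))


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write a signal as 16-bit PCM WAV."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    data = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), signal.sample_rate, data)


def _feature_columns(n: int = 120) -> list[str]:
    return [f"f{i:03d}" for i in range(1, n + 1)]


def features_to_frame(
    vectors: list[FeatureVector], genders: list[str] | None = None
) -> pd.DataFrame:
    """Tabulate feature vectors: speaker_id, age, gender, vowel, f001..f120."""
    if not vectors:
        raise ValueError("no feature vectors to tabulate")
    n = vectors[0].values.size
    rows = {
        "speaker_id": [v.speaker_id for v in vectors],
        "age": [v.age_label for v in vectors],
        "gender": genders if genders is not None else ["unknown"] * len(vectors),
        "vowel": [v.vowel_label for v in vectors],
    }
    values = np.stack([v.values for v in vectors])
    return pd.concat(
        [pd.DataFrame(rows), pd.DataFrame(values, columns=_feature_columns(n))],
        axis=1,
    )


def save_feature_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"speaker_id": str})
    missing = [c for c in ("speaker_id", "age", "vowel") if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table {path} lacks columns {missing}")
    return frame
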