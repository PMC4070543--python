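"""Synthetic corpora with the structure the age-estimation method assumes.

Two levels of realism:

* waveform level — source-filter synthesis of sustained vowels (a glottal
  impulse train with small jitter through cascaded second-order formant
  resonators) whose fundamental frequency and formant scale drift with age,
  exercising the MFCC front end end-to-end;

* feature level — Gaussian clusters with controllable between-class
  separation and an optional *complementary* design in which each stream
  ("vowel") separates only a subset of the age classes, the regime in which
  decision fusion has something to gain.

Generator constants (formant tables, developmental slopes) are plausible
child-speech magnitudes chosen to make age classes learnable but
overlapping; they are knobs of this generator, not measurements of any
particular corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .features import VOWELS, AudioSignal

__all__ = [
    "VowelSpec",
    "AgeModel",
    "CorpusConfig",
    "DEFAULT_VOWEL_SPECS",
    "synth_vowel",
    "corpus_layout",
    "iter_corpus",
    "synth_corpus",
    "synth_feature_clusters",
]


@dataclass(frozen=True)
class VowelSpec:
    """Formant targets (Hz) defining one vowel's spectral envelope."""

    label: str
    formants: tuple[float, float, float]
    bandwidths: tuple[float, float, float] = (80.0, 120.0, 180.0)

    def __post_init__(self) -> None:
        f1, f2, f3 = self.formants
        if not 0 < f1 < f2 < f3:
            raise ValueError("formants must be positive and strictly increasing")


# child-typical patterning: /a/ open (high F1, mid F2), /i/ close front
# (low F1, high F2), /u/ close back (low F1, low F2), schwa central
DEFAULT_VOWEL_SPECS: dict[str, VowelSpec] = {
    "a": VowelSpec("a", (950.0, 1750.0, 3300.0)),
    "e": VowelSpec("e", (650.0, 2600.0, 3500.0)),
    "ə": VowelSpec("ə", (600.0, 1700.0, 3200.0)),
    "i": VowelSpec("i", (400.0, 3200.0, 3900.0)),
    "o": VowelSpec("o", (550.0, 1050.0, 3100.0)),
    "u": VowelSpec("u", (430.0, 1350.0, 3600.0)),
}


def _linear_by_age(ages: Sequence[int], start: float, stop: float) -> dict[int, float]:
    ages = list(ages)
    vals = np.linspace(start, stop, len(ages))
    return dict(zip(ages, vals.tolist()))


@dataclass(frozen=True)
class AgeModel:
    """Developmental trends: f0 and formant scale decline with age.

    Defaults: mean f0 falls linearly 280 -> 230 Hz from age 7 to 12, the
    formant scale factor falls 1% per year (vocal tract lengthening), and
    speakers scatter around their age means with the given relative SDs.
    """

    f0_by_age: Mapping[int, float] = field(
        default_factory=lambda: _linear_by_age(range(7, 13), 280.0, 230.0)
    )
    formant_scale_by_age: Mapping[int, float] = field(
        default_factory=lambda: {age: 1.0 - 0.01 * (age - 7) for age in range(7, 13)}
    )
    f0_speaker_rel_sd: float = 0.05
    scale_speaker_rel_sd: float = 0.02

    def __post_init__(self) -> None:
        for name, table in (
            ("f0_by_age", self.f0_by_age),
            ("formant_scale_by_age", self.formant_scale_by_age),
        ):
            ages = sorted(table)
            vals = [table[a] for a in ages]
            if min(vals) <= 0:
                raise ValueError(f"{name} values must be positive")
            if any(b > a for a, b in zip(vals, vals[1:])):
                # declared monotone non-increasing with age
                raise ValueError(f"{name} must be non-increasing in age")


@dataclass(frozen=True)
class CorpusConfig:
    """Layout of the generated corpus; defaults mirror a 60-per-cell grid
    of ages 7-12 by six vowels (360 speakers, 2160 utterances of 5 s at
    20 kHz)."""

    n_speakers_per_age: int = 60
    ages: tuple[int, ...] = tuple(range(7, 13))
    vowels: tuple[str, ...] = VOWELS
    duration_s: float = 5.0
    sample_rate: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_speakers_per_age < 1 or self.duration_s <= 0:
            raise ValueError("counts and duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


def synth_vowel(
    spec: VowelSpec,
    f0: float,
    scale: float = 1.0,
    duration: float = 5.0,
    sample_rate: int = 20000,
    seed: int = 0,
    jitter: float = 0.005,
    noise_level: float = 0.02,
) -> AudioSignal:
    """Source-filter synthesis of one sustained vowel.

    A glottal impulse train at ``f0`` (with small cycle-to-cycle jitter) plus
    low-level aspiration noise is passed through cascaded two-pole resonators
    at ``scale * F1..F3``; the output is peak-normalized to [-1, 1].
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    nyquist = sample_rate / 2.0
    if scale * spec.formants[-1] >= nyquist:
        raise ValueError(
            f"scaled formant {scale * spec.formants[-1]:.0f} Hz is at or above "
            f"Nyquist ({nyquist:.0f} Hz)"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    source = np.zeros(n)
    t = 0.0
    while t < n:
        source[int(t)] = 1.0
        period = sample_rate / f0
        t += period * max(0.5, 1.0 + jitter * rng.standard_normal())
    source += noise_level * rng.standard_normal(n)
    out = source
    for formant, bandwidth in zip(spec.formants, spec.bandwidths):
        r = np.exp(-np.pi * bandwidth / sample_rate)
        theta = 2.0 * np.pi * scale * formant / sample_rate
        out = lfilter([1.0 - r], [1.0, -2.0 * r * np.cos(theta), r * r], out)
    peak = np.max(np.abs(out))
    return AudioSignal(samples=out / peak, sample_rate=sample_rate)


def corpus_layout(config: CorpusConfig) -> pd.DataFrame:
    """The corpus grid (speaker_id, age, gender, vowel), no audio."""
    rows = []
    speaker = 0
    for age in config.ages:
        for j in range(config.n_speakers_per_age):
            sid = f"s{speaker:04d}"
            gender = "F" if j % 2 else "M"
            for vowel in config.vowels:
                rows.append((sid, age, gender, vowel))
            speaker += 1
    return pd.DataFrame(rows, columns=["speaker_id", "age", "gender", "vowel"])


def iter_corpus(
    config: CorpusConfig,
    age_model: AgeModel | None = None,
    vowel_specs: Mapping[str, VowelSpec] | None = None,
) -> Iterator[tuple[dict, AudioSignal]]:
    """Yield (metadata, waveform) pairs; deterministic under config.seed.

    Each speaker draws one multiplicative f0 offset and one formant-scale
    offset shared across their vowels, so the six utterances of a child are
    acoustically linked the way real recordings are.
    """
    age_model = age_model or AgeModel()
    vowel_specs = vowel_specs or DEFAULT_VOWEL_SPECS
    rng = np.random.default_rng(config.seed)
    layout = corpus_layout(config)
    for sid, group in layout.groupby("speaker_id", sort=True):
        age = int(group["age"].iloc[0])
        f0_mult = 1.0 + age_model.f0_speaker_rel_sd * rng.standard_normal()
        scale_mult = 1.0 + age_model.scale_speaker_rel_sd * rng.standard_normal()
        f0 = age_model.f0_by_age[age] * max(0.5, f0_mult)
        scale = age_model.formant_scale_by_age[age] * max(0.5, scale_mult)
        for _, row in group.iterrows():
            utt_seed = int(rng.integers(2**31))
            signal = synth_vowel(
                vowel_specs[row["vowel"]],
                f0=f0,
                scale=scale,
                duration=config.duration_s,
                sample_rate=config.sample_rate,
                seed=utt_seed,
            )
            yield dict(row), signal


def synth_corpus(
    config: CorpusConfig,
    age_model: AgeModel | None = None,
    vowel_specs: Mapping[str, VowelSpec] | None = None,
) -> list[tuple[dict, AudioSignal]]:
    """Materialize the whole corpus in memory (use iter_corpus for big runs)."""
    return list(iter_corpus(config, age_model, vowel_specs))


def synth_feature_clusters(
    n_classes: int = 6,
    n_per_class: int = 50,
    dim: int = 6,
    separation: float = 4.0,
    seed: int = 0,
    complementary_map: Mapping[str, Sequence[int]] | None = None,
    streams: Sequence[str] | None = None,
    stream_offset: float = 0.0,
) -> pd.DataFrame:
    """Gaussian feature clusters shaped like the per-vowel feature tables.

    Classes are labeled as ages 7..(6 + n_classes); within-class SD is 1, so
    ``separation`` is the between-class mean distance in SD units.  Each
    "speaker" contributes one sample per stream.  With ``complementary_map``,
    stream ``s`` keeps distinct means only for the classes in its subset —
    the others collapse onto a common mean — so no stream can separate all
    classes but the ensemble can.  ``stream_offset`` shifts each stream along
    its own random direction, making streams identifiable to a vowel gate.
    """
    if dim < 1 or n_per_class < 1 or n_classes < 2:
        raise ValueError("need dim >= 1, n_per_class >= 1, n_classes >= 2")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    classes = list(range(7, 7 + n_classes))
    if streams is None:
        streams = list(complementary_map) if complementary_map else ["a"]
    if complementary_map is not None:
        covered = set().union(*(set(v) for v in complementary_map.values()))
        if not covered <= set(classes):
            raise ValueError(
                f"complementary_map names classes outside {classes}"
            )
        if set(streams) != set(complementary_map):
            raise ValueError("streams must match complementary_map keys")

    if dim >= n_classes:
        means = np.zeros((n_classes, dim))
        means[np.arange(n_classes), np.arange(n_classes)] = separation / np.sqrt(2)
    else:
        directions = rng.standard_normal((n_classes, dim))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        means = directions * separation / np.sqrt(2)

    offsets = {}
    for s in streams:
        direction = rng.standard_normal(dim)
        offsets[s] = stream_offset * direction / np.linalg.norm(direction)

    rows = []
    values = []
    speaker = 0
    for ci, cls in enumerate(classes):
        for _ in range(n_per_class):
            sid = f"s{speaker:04d}"
            for s in streams:
                if complementary_map is not None and cls not in complementary_map[s]:
                    mean = np.zeros(dim)  # collapsed: uninformative for cls
                else:
                    mean = means[ci]
                x = mean + offsets[s] + rng.standard_normal(dim)
                rows.append((sid, cls, "unknown", s))
                values.append(x)
            speaker += 1
    meta = pd.DataFrame(rows, columns=["speaker_id", "age", "gender", "vowel"])
    feats = pd.DataFrame(
        np.asarray(values), columns=[f"f{j + 1:03d}" for j in range(dim)]
    )
    return pd.concat([meta, feats], axis=1)
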