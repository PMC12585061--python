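"""Audio standardization front-end.

Every recording entering the pipeline is reduced to a fixed contract: mono,
a common sample rate (22,050 Hz by default), peak amplitude 1, and a fixed
duration (6 s by default, i.e. 132,300 samples). Clips shorter than the
target are zero-padded at the tail; longer clips keep their leading prefix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "RawRecording",
    "PreprocessConfig",
    "StandardizedClip",
    "load_audio",
    "resample",
    "peak_normalize",
    "standardize_duration",
    "standardize",
    "load_manifest",
    "write_wav",
]


@dataclass
class PreprocessConfig:
    """Target acquisition constants.

    ``samples`` is always derived as ``round(target_rate * duration)``;
    at the defaults (22,050 Hz, 6 s) that is 132,300 samples per clip.
    A 4 s profile suits datasets segmented into 4-second windows.
    """

    target_rate: int = 22050
    duration: float = 6.0

    @property
    def samples(self) -> int:
        return int(round(self.target_rate * self.duration))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PreprocessConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: raw[k] for k in ("target_rate", "duration") if k in raw})

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"target_rate": self.target_rate, "duration": self.duration}, fh)


@dataclass
class RawRecording:
    """Mono waveform at its native rate, before standardization."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("RawRecording requires a non-empty 1-D sample array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class StandardizedClip:
    """Fixed-length, peak-normalized mono waveform at the configured rate."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    def __len__(self) -> int:
        return self.samples.size


def load_audio(path: str | os.PathLike, config: Optional[PreprocessConfig] = None) -> RawRecording:
    """Read a WAV file (PCM or float) into a mono :class:`RawRecording`.

    Stereo and multi-channel files are down-mixed by averaging channels.
    Integer PCM is rescaled to [-1, 1]. The native sample rate is kept;
    resampling happens later in :func:`standardize`.
    """
    try:
        rate, data = wavfile.read(os.fspath(path))
    except Exception as exc:  # wavfile raises ValueError on malformed RIFF
        raise IOError(f"could not read WAV file {os.fspath(path)!r}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio in {os.fspath(path)!r}")
    x = np.asarray(data, dtype=np.float64)
    if np.issubdtype(data.dtype, np.integer):
        x = x / float(np.iinfo(data.dtype).max)
    if x.ndim > 1:
        x = x.mean(axis=1)
    return RawRecording(samples=x, sample_rate=int(rate), source_id=str(path))


def write_wav(path: str | os.PathLike, samples: Sequence[float], rate: int) -> None:
    """Write a float32 WAV file (round-trips losslessly through load_audio)."""
    wavfile.write(os.fspath(path), int(rate), np.asarray(samples, dtype=np.float32))


def resample(rec: RawRecording, target_rate: int) -> RawRecording:
    """Band-limited polyphase resampling to ``target_rate``.

    Output length is round(len * target_rate / source_rate).
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == rec.sample_rate:
        return RawRecording(rec.samples.copy(), rec.sample_rate, rec.source_id, rec.label)
    frac = Fraction(int(target_rate), int(rec.sample_rate))
    y = resample_poly(rec.samples, frac.numerator, frac.denominator)
    n_out = int(round(rec.samples.size * target_rate / rec.sample_rate))
    y = standardize_duration(y, n_out)  # polyphase output can differ by a sample
    return RawRecording(y, int(target_rate), rec.source_id, rec.label)


def peak_normalize(x: Sequence[float]) -> np.ndarray:
    """Scale a waveform so its peak absolute amplitude is 1.

    All-zero input is returned unchanged (the divide-by-zero guard).
    """
    x = np.asarray(x, dtype=np.float64)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak == 0.0:
        return x.copy()
    return x / peak


def standardize_duration(x: Sequence[float], samples: int) -> np.ndarray:
    """Force a waveform to exactly ``samples`` values.

    Identity if the length already matches, tail zero-padding if shorter,
    and leading-prefix truncation if longer.
    """
    if samples <= 0:
        raise ValueError("samples must be positive")
    x = np.asarray(x, dtype=np.float64)
    if x.size == samples:
        return x.copy()
    if x.size < samples:
        return np.concatenate([x, np.zeros(samples - x.size)])
    return x[:samples].copy()


def standardize(rec: RawRecording, config: Optional[PreprocessConfig] = None) -> StandardizedClip:
    """Full standardization: resample, peak-normalize, fix duration."""
    config = config or PreprocessConfig()
    rec = resample(rec, config.target_rate)
    x = standardize_duration(peak_normalize(rec.samples), config.samples)
    return StandardizedClip(x, config.target_rate, rec.source_id, rec.label)


def load_manifest(path: str | os.PathLike, config: Optional[PreprocessConfig] = None) -> list[StandardizedClip]:
    """Load a ``path,label`` CSV manifest into standardized clips.

    Relative paths in the manifest are resolved against the manifest's
    own directory. No assumption is made about how many rows there are.
    """
    config = config or PreprocessConfig()
    table = pd.read_csv(path)
    if not {"path", "label"}.issubset(table.columns):
        raise ValueError("manifest must have columns 'path' and 'label'")
    base = os.path.dirname(os.fspath(path))
    clips = []
    for row in table.itertuples(index=False):
        wav_path = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        rec = load_audio(wav_path, config)
        rec.label = str(row.label)
        clip = standardize(rec, config)
        clip.label = str(row.label)
        clips.append(clip)
    return clips
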