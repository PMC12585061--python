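"""Synthetic respiratory-sound generator.

Produces seeded, class-conditional recordings whose spectral structure
mirrors the frequency bands where the respective pathologies concentrate
energy on auscultation: asthmatic wheeze at 400-600 Hz, COPD wheeze at
200-350 Hz, pneumonia crackles at 300-800 Hz, plus a healthy profile
(breath noise only) and a bronchial profile (interpolated wheeze band
with sparse crackles — this profile is an invention of this package, the
class is not acoustically characterized anywhere authoritative here).

Each clip is a smooth breath-cycle envelope multiplying the class events
(amplitude-modulated narrowband wheeze tones and/or Poisson-timed damped
crackle transients) plus a Gaussian noise floor, peak-normalized.

The generator is deliberately simple: it gives tests a learnably
class-structured dataset, not a realistic auscultation timbre.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .preprocess import write_wav

__all__ = [
    "ClassProfile",
    "SynthDatasetSpec",
    "DEFAULT_PROFILES",
    "breath_envelope",
    "synth_wheeze",
    "synth_crackles",
    "synth_clip",
    "generate_dataset",
    "generate_clips",
]


@dataclass
class ClassProfile:
    """Acoustic recipe for one respiratory class."""

    name: str
    wheeze_band: Optional[tuple[float, float]] = None   # Hz
    wheeze_gain: float = 1.0
    crackle_rate: float = 0.0                           # events / second
    crackle_band: Optional[tuple[float, float]] = None  # Hz
    breath_rate: float = 18.0                           # cycles / minute
    noise_floor: float = 0.05                           # Gaussian sigma

    def __post_init__(self) -> None:
        for band in (self.wheeze_band, self.crackle_band):
            if band is not None and not (0 < band[0] <= band[1]):
                raise ValueError(f"invalid band {band} for class {self.name}")
        if self.crackle_rate < 0 or self.breath_rate <= 0:
            raise ValueError("rates must be non-negative (breath rate positive)")


DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "asthma": ClassProfile("asthma", wheeze_band=(400.0, 600.0)),
    "copd": ClassProfile("copd", wheeze_band=(200.0, 350.0)),
    "pneumonia": ClassProfile("pneumonia", crackle_rate=10.0, crackle_band=(300.0, 800.0)),
    "healthy": ClassProfile("healthy"),
    "bronchial": ClassProfile("bronchial", wheeze_band=(300.0, 450.0),
                              crackle_rate=2.0, crackle_band=(300.0, 800.0)),
}


@dataclass
class SynthDatasetSpec:
    classes: Sequence[ClassProfile] = field(
        default_factory=lambda: list(DEFAULT_PROFILES.values()))
    per_class: int = 20
    duration: float = 6.0
    sample_rate: int = 22050
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_class < 1 or not self.classes:
            raise ValueError("need at least one class and one clip per class")


def breath_envelope(duration: float, breath_rate: float, rng: np.random.Generator,
                    sample_rate: int = 22050) -> np.ndarray:
    """Smooth periodic amplitude envelope in [0, 1], jittered per cycle.

    Each cycle is a raised-cosine hump of period 60/breath_rate seconds;
    per-cycle amplitude and duration are jittered by ~10%.
    """
    if breath_rate <= 0:
        raise ValueError("breath_rate must be positive")
    n = int(round(duration * sample_rate))
    period = 60.0 / breath_rate
    env = np.zeros(n)
    t0 = 0.0
    while t0 < duration:
        cycle = period * (1 + 0.1 * rng.standard_normal())
        cycle = max(cycle, 0.2 * period)
        amp = np.clip(1 + 0.1 * rng.standard_normal(), 0.0, 1.0)
        i0, i1 = int(t0 * sample_rate), min(int((t0 + cycle) * sample_rate), n)
        if i1 > i0:
            phase = np.linspace(0, 2 * np.pi, i1 - i0, endpoint=False)
            env[i0:i1] = amp * 0.5 * (1 - np.cos(phase))
        t0 += cycle
    return np.clip(env, 0.0, 1.0)


def synth_wheeze(duration: float, band: tuple[float, float], rng: np.random.Generator,
                 sample_rate: int = 22050) -> np.ndarray:
    """Amplitude-modulated narrowband tone drifting inside ``band``.

    The instantaneous frequency performs a slow smoothed random walk
    confined to the band, so spectral energy stays in (and tightly
    around) the band.
    """
    n = int(round(duration * sample_rate))
    lo, hi = band
    if hi > lo:
        walk = np.cumsum(rng.standard_normal(n))
        walk = (walk - walk.min()) / max(np.ptp(walk), 1e-12)  # [0, 1]
        # smooth the walk so frequency drift is slow (sub-Hz modulation)
        kernel = np.ones(sample_rate // 10) / (sample_rate // 10)
        walk = np.convolve(walk, kernel, mode="same")
        freq = lo + (hi - lo) * np.clip(walk, 0, 1)
    else:
        freq = np.full(n, lo)
    phase = 2 * np.pi * np.cumsum(freq) / sample_rate
    am = 0.7 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.5, 2.0) * np.arange(n) / sample_rate
                            + rng.uniform(0, 2 * np.pi))
    return am * np.sin(phase)


def synth_crackles(duration: float, rate: float, band: tuple[float, float],
                   rng: np.random.Generator, sample_rate: int = 22050) -> np.ndarray:
    """Poisson-timed, band-filtered damped impulses (< 20 ms transients)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    n = int(round(duration * sample_rate))
    out = np.zeros(n)
    count = rng.poisson(rate * duration)
    if count == 0:
        return out
    event_len = int(0.015 * sample_rate)  # 15 ms damped burst
    decay = np.exp(-np.arange(event_len) / (0.003 * sample_rate))
    for start in rng.integers(0, max(n - event_len, 1), size=count):
        burst = decay * rng.standard_normal(event_len)
        out[start:start + event_len] += burst[: n - start]
    lo, hi = band
    nyq = sample_rate / 2
    sos = butter(4, [lo / nyq, min(hi / nyq, 0.99)], btype="band", output="sos")
    return sosfilt(sos, out)


def synth_clip(profile: ClassProfile, duration: float, sample_rate: int,
               rng: np.random.Generator) -> np.ndarray:
    """One peak-normalized synthetic recording for ``profile``."""
    n = int(round(duration * sample_rate))
    env = breath_envelope(duration, profile.breath_rate, rng, sample_rate)
    x = np.zeros(n)
    if profile.wheeze_band is not None:
        x += profile.wheeze_gain * synth_wheeze(duration, profile.wheeze_band, rng, sample_rate)
    if profile.crackle_rate > 0 and profile.crackle_band is not None:
        x += synth_crackles(duration, profile.crackle_rate, profile.crackle_band, rng, sample_rate)
    x = env * x + profile.noise_floor * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def generate_clips(spec: SynthDatasetSpec) -> tuple[np.ndarray, list[str]]:
    """In-memory dataset: (clips array [n, samples], labels). Seeded."""
    rng = np.random.default_rng(spec.seed)
    clips, labels = [], []
    for profile in spec.classes:
        for _ in range(spec.per_class):
            clips.append(synth_clip(profile, spec.duration, spec.sample_rate, rng))
            labels.append(profile.name)
    return np.stack(clips), labels


def generate_dataset(spec: SynthDatasetSpec, out_dir: str | os.PathLike) -> str:
    """Write WAV files plus a ``path,label`` CSV manifest; returns manifest path."""
    out_dir = os.fspath(out_dir)
    try:
        os.makedirs(out_dir, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir!r}: {exc}") from exc
    clips, labels = generate_clips(spec)
    rows = []
    for i, (clip, label) in enumerate(zip(clips, labels)):
        name = f"{label}_{i:04d}.wav"
        write_wav(os.path.join(out_dir, name), clip, spec.sample_rate)
        rows.append({"path": name, "label": label})
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
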