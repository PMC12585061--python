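"""Triple-stream acoustic feature extraction.

Three fixed-grid representations are computed per standardized clip:

* **MFCC** — 20 cepstral coefficients from a 40-filter mel bank over a
  Hamming-windowed STFT (2048-sample window, 512-sample hop). The DCT is
  the plain cosine sum ``sum_k log(S_k) cos(pi p (k+1/2)/M)`` with no
  orthonormal scaling.
* **Wavelet** — a 5-level Daubechies-1 (Haar) decomposition; the six
  sub-bands (a5, d5..d1, coarse to fine) are reduced to per-frame mean
  absolute envelopes and interpolated along the band axis to 20 rows.
* **Log-mel spectrogram** — 128 HTK-scale mel filters over a
  Hann-windowed STFT, in dB: ``10 log10(S + 1e-10)``.

Framing is centered (reflect padding), so a clip of L samples yields
``1 + L // hop`` frames — 259 frames for the default 6 s / 22,050 Hz clip.
All three matrices share that time axis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pywt
import yaml

from .preprocess import StandardizedClip

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "FeatureBundle",
    "make_window",
    "frame_count",
    "stft",
    "power_spectrum",
    "hz_to_mel",
    "mel_to_hz",
    "build_filterbank",
    "mel_energies",
    "mfcc",
    "wavelet_features",
    "mel_spectrogram",
    "extract_features",
    "bundle",
    "save_bundle",
    "load_bundle",
]

LOG_EPS = 1e-10


@dataclass
class FeatureConfig:
    """Spectral front-end constants (defined at 22,050 Hz)."""

    sample_rate: int = 22050
    n_fft: int = 2048          # STFT window length N
    hop: int = 512             # hop H
    n_mfcc: int = 20
    n_mels_mfcc: int = 40      # mel filters feeding the cepstral DCT
    n_mels: int = 128          # mel-spectrogram bands
    f_min: float = 0.0
    f_max: Optional[float] = None   # defaults to Nyquist
    dwt_levels: int = 5
    wavelet: str = "db1"
    wavelet_rows: int = 20
    log_eps: float = LOG_EPS

    def __post_init__(self) -> None:
        if self.n_fft < self.hop or self.hop <= 0:
            raise ValueError("require n_fft >= hop > 0")
        if self.f_max is None:
            self.f_max = self.sample_rate / 2

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "FeatureConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class FeatureMatrix:
    """One real-valued time-frequency (or time-band) matrix."""

    values: np.ndarray
    kind: str  # {"mfcc", "wavelet", "melspec"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.kind} feature matrix")


@dataclass
class FeatureBundle:
    """Batched, channel-augmented feature tensors (B x rows x frames x 1)."""

    x_mfcc: np.ndarray
    x_wav: np.ndarray
    x_mel: np.ndarray
    labels: Optional[np.ndarray] = None

    @property
    def batch_size(self) -> int:
        return self.x_mfcc.shape[0]


def make_window(kind: str, n: int) -> np.ndarray:
    """Symmetric Hamming or Hann window of length ``n``."""
    if n < 2:
        raise ValueError("window length must be >= 2")
    idx = np.arange(n)
    if kind == "hamming":
        return 0.54 - 0.46 * np.cos(2 * np.pi * idx / (n - 1))
    if kind == "hann":
        return 0.5 * (1 - np.cos(2 * np.pi * idx / (n - 1)))
    raise ValueError(f"unknown window kind {kind!r}")


def frame_count(n_samples: int, hop: int) -> int:
    """Frames under centered framing: 1 + floor(L / H)."""
    return 1 + n_samples // hop


def stft(x: np.ndarray | StandardizedClip, cfg: FeatureConfig, window: str = "hamming") -> np.ndarray:
    """One-sided STFT, bins 0..N/2 by frames, centered via reflect padding."""
    if isinstance(x, StandardizedClip):
        x = x.samples
    x = np.asarray(x, dtype=np.float64)
    n, h = cfg.n_fft, cfg.hop
    w = make_window(window, n)
    pad = n // 2
    xp = np.pad(x, pad, mode="reflect")
    m = frame_count(x.size, h)
    frames = np.lib.stride_tricks.sliding_window_view(xp, n)[:: h][:m]
    return np.fft.rfft(frames * w, n=n, axis=1).T  # (n//2+1, m)


def power_spectrum(spec: np.ndarray) -> np.ndarray:
    """P[k, m] = |STFT[k, m]|^2."""
    return np.abs(spec) ** 2


def hz_to_mel(f):
    """HTK mel scale: mel(f) = 2595 log10(1 + f/700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def build_filterbank(
    num_filters: int, n_fft: int, sample_rate: int,
    f_min: float = 0.0, f_max: Optional[float] = None,
) -> np.ndarray:
    """Triangular mel filterbank, shape (num_filters, n_fft//2 + 1).

    Filter centers are equispaced on the mel axis between ``f_min`` and
    ``f_max``; no area normalization is applied.
    """
    if f_max is None:
        f_max = sample_rate / 2
    if num_filters < 1:
        raise ValueError("need at least one filter")
    if not (0 <= f_min < f_max <= sample_rate / 2):
        raise ValueError("infeasible band edges")
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(f_min), hz_to_mel(f_max), num_filters + 2))
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    fb = np.zeros((num_filters, bin_freqs.size))
    for b in range(num_filters):
        left, center, right = edges_hz[b], edges_hz[b + 1], edges_hz[b + 2]
        rising = (bin_freqs - left) / (center - left)
        falling = (right - bin_freqs) / (right - center)
        fb[b] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def filterbank_centers(num_filters: int, sample_rate: int,
                       f_min: float = 0.0, f_max: Optional[float] = None) -> np.ndarray:
    """Center frequency (Hz) of each triangular filter."""
    if f_max is None:
        f_max = sample_rate / 2
    edges = mel_to_hz(np.linspace(hz_to_mel(f_min), hz_to_mel(f_max), num_filters + 2))
    return edges[1:-1]


def mel_energies(power: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Mel-filtered spectrum S[b, m] = sum_k P[k, m] * fb[b, k]."""
    return fb @ power


def mfcc(clip: StandardizedClip | np.ndarray, cfg: Optional[FeatureConfig] = None) -> FeatureMatrix:
    """20 x frames cepstral matrix (plain cosine-sum DCT of log mel energies)."""
    cfg = cfg or FeatureConfig()
    p_spec = power_spectrum(stft(clip, cfg, window="hamming"))
    fb = build_filterbank(cfg.n_mels_mfcc, cfg.n_fft, cfg.sample_rate, cfg.f_min, cfg.f_max)
    log_s = np.log(mel_energies(p_spec, fb) + cfg.log_eps)  # (M, frames)
    m = cfg.n_mels_mfcc
    p = np.arange(cfg.n_mfcc)
    basis = np.cos(np.pi * p[:, None] * (np.arange(m) + 0.5) / m)  # (20, M)
    return FeatureMatrix(basis @ log_s, kind="mfcc")


def _segment_envelope(coeffs: np.ndarray, n_frames: int) -> np.ndarray:
    """Mean absolute value over ``n_frames`` near-equal segments."""
    a = np.abs(np.asarray(coeffs, dtype=np.float64))
    if a.size >= n_frames:
        bounds = np.floor(np.linspace(0, a.size, n_frames + 1)).astype(int)
        csum = np.concatenate([[0.0], np.cumsum(a)])
        lengths = np.maximum(bounds[1:] - bounds[:-1], 1)
        return (csum[np.minimum(bounds[:-1] + lengths, a.size)] - csum[bounds[:-1]]) / lengths
    # shorter sub-band than frame grid: linear interpolation of the envelope
    return np.interp(np.linspace(0, a.size - 1, n_frames), np.arange(a.size), a)


def wavelet_features(clip: StandardizedClip | np.ndarray, cfg: Optional[FeatureConfig] = None) -> FeatureMatrix:
    """Multi-resolution 20 x frames matrix from a 5-level db1 decomposition.

    Row order runs coarse (approximation a5) to fine (detail d1); the six
    sub-band envelopes are linearly interpolated to ``wavelet_rows`` rows.
    """
    cfg = cfg or FeatureConfig()
    x = clip.samples if isinstance(clip, StandardizedClip) else np.asarray(clip, dtype=np.float64)
    if x.size < 2 ** cfg.dwt_levels:
        raise ValueError(f"clip shorter than 2^{cfg.dwt_levels} samples")
    coeffs = pywt.wavedec(x, cfg.wavelet, level=cfg.dwt_levels)  # [a5, d5, ..., d1]
    n_frames = frame_count(x.size, cfg.hop)
    env = np.stack([_segment_envelope(c, n_frames) for c in coeffs])  # (levels+1, frames)
    src = np.arange(env.shape[0], dtype=np.float64)
    tgt = np.linspace(0, env.shape[0] - 1, cfg.wavelet_rows)
    i0 = np.minimum(np.floor(tgt).astype(int), env.shape[0] - 2)
    w = (tgt - i0)[:, None]
    return FeatureMatrix(env[i0] * (1 - w) + env[i0 + 1] * w, kind="wavelet")


def mel_spectrogram(clip: StandardizedClip | np.ndarray, cfg: Optional[FeatureConfig] = None) -> FeatureMatrix:
    """128 x frames log-mel spectrogram in dB, floored at -100 dB."""
    cfg = cfg or FeatureConfig()
    p_spec = power_spectrum(stft(clip, cfg, window="hann"))
    fb = build_filterbank(cfg.n_mels, cfg.n_fft, cfg.sample_rate, cfg.f_min, cfg.f_max)
    return FeatureMatrix(10.0 * np.log10(mel_energies(p_spec, fb) + cfg.log_eps), kind="melspec")


def extract_features(clip: StandardizedClip, cfg: Optional[FeatureConfig] = None) -> dict[str, FeatureMatrix]:
    cfg = cfg or FeatureConfig()
    return {
        "mfcc": mfcc(clip, cfg),
        "wavelet": wavelet_features(clip, cfg),
        "melspec": mel_spectrogram(clip, cfg),
    }


def bundle(per_clip: Sequence[dict[str, FeatureMatrix]],
           labels: Optional[Sequence] = None) -> FeatureBundle:
    """Stack per-clip feature dicts into batched tensors with a channel axis."""
    if not per_clip:
        raise ValueError("empty batch")
    for key in ("mfcc", "wavelet", "melspec"):
        shapes = {d[key].values.shape for d in per_clip}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent {key} shapes across batch: {shapes}")
    stack = lambda key: np.stack([d[key].values for d in per_clip])[..., None]
    return FeatureBundle(
        x_mfcc=stack("mfcc"),
        x_wav=stack("wavelet"),
        x_mel=stack("melspec"),
        labels=None if labels is None else np.asarray(labels),
    )


def save_bundle(path: str | os.PathLike, fb: FeatureBundle) -> None:
    arrays = {"mfcc": fb.x_mfcc, "wav": fb.x_wav, "mel": fb.x_mel}
    if fb.labels is not None:
        arrays["labels"] = fb.labels
    np.savez(os.fspath(path), **arrays)


def load_bundle(path: str | os.PathLike) -> FeatureBundle:
    with np.load(os.fspath(path), allow_pickle=False) as z:
        return FeatureBundle(
            x_mfcc=z["mfcc"], x_wav=z["wav"], x_mel=z["mel"],
            labels=z["labels"] if "labels" in z else None,
        )
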