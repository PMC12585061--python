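"""Formula-level audio augmentation with intensity scheduling.

Waveform operators (time stretch, pitch shift, dynamic-range compression,
cutmix/mixup, room reverb, colored noise) act on raw clips before feature
extraction; spectral operators (VTLP, formant shift, frequency dropout,
SpecAugment) act on spectrogram-like matrices afterwards.

The policy layer draws, per sample, an intensity-dependent number of
operators (light 1-2, medium 2-4, heavy 3-6) with probability-weighted
selection P(op_i) = p_i * intensity_factor, and scales every operator's
parameter range about its neutral point by the intensity scale factor
(0.5x / 1.0x / 1.5x). All randomness flows from one explicit
``numpy.random.Generator``; there is no hidden global state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .features import make_window

__all__ = [
    "AugmentOp",
    "IntensityPolicy",
    "AugmentedSample",
    "DEFAULT_OPS",
    "time_stretch",
    "pitch_shift",
    "dynamic_range_compress",
    "vtlp",
    "formant_shift",
    "freq_dropout",
    "mixup",
    "cutmix",
    "room_reverb",
    "colored_noise",
    "spec_augment",
    "sample_policy",
    "apply_waveform_ops",
]


# ---------------------------------------------------------------------------
# phase vocoder machinery (time stretch / pitch shift)

def _stft_cols(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    w = make_window("hann", n_fft)
    pad = n_fft // 2
    xp = np.pad(x, pad, mode="reflect")
    m = 1 + x.size // hop
    frames = np.lib.stride_tricks.sliding_window_view(xp, n_fft)[::hop][:m]
    return np.fft.rfft(frames * w, axis=1).T


def _istft(cols: np.ndarray, n_fft: int, hop: int, length: int) -> np.ndarray:
    w = make_window("hann", n_fft)
    n_frames = cols.shape[1]
    total = n_fft + hop * (n_frames - 1)
    y = np.zeros(total)
    norm = np.zeros(total)
    frames = np.fft.irfft(cols.T, n=n_fft, axis=1) * w
    for t in range(n_frames):
        y[t * hop: t * hop + n_fft] += frames[t]
        norm[t * hop: t * hop + n_fft] += w ** 2
    y = y / np.maximum(norm, 1e-12)
    pad = n_fft // 2
    y = y[pad: pad + length]
    if y.size < length:
        y = np.concatenate([y, np.zeros(length - y.size)])
    return y


def _phase_vocoder(cols: np.ndarray, rate: float, n_fft: int, hop: int) -> np.ndarray:
    time_steps = np.arange(0, cols.shape[1], rate)
    phi_advance = 2 * np.pi * hop * np.arange(cols.shape[0]) / n_fft
    padded = np.pad(cols, [(0, 0), (0, 2)])
    out = np.zeros((cols.shape[0], time_steps.size), dtype=complex)
    phase_acc = np.angle(padded[:, 0])
    for t, step in enumerate(time_steps):
        i = int(step)
        frac = step - i
        c0, c1 = padded[:, i], padded[:, i + 1]
        mag = (1 - frac) * np.abs(c0) + frac * np.abs(c1)
        out[:, t] = mag * np.exp(1j * phase_acc)
        dphi = np.angle(c1) - np.angle(c0) - phi_advance
        dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
        phase_acc = phase_acc + phi_advance + dphi
    return out


def time_stretch(x: np.ndarray, rate: float, n_fft: int = 2048, hop: int = 512) -> np.ndarray:
    """Phase-vocoder tempo change: output length round(len/rate), pitch kept."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    x = np.asarray(x, dtype=np.float64)
    if rate == 1.0:
        return x.copy()
    cols = _phase_vocoder(_stft_cols(x, n_fft, hop), rate, n_fft, hop)
    return _istft(cols, n_fft, hop, int(round(x.size / rate)))


def pitch_shift(x: np.ndarray, n_semitones: float, sample_rate: int = 22050,
                n_fft: int = 2048, hop: int = 512) -> np.ndarray:
    """Shift spectral content by ``2^(n/12)`` at unchanged length.

    Implemented as a phase-vocoder stretch followed by resampling back to
    the original length, which scales every frequency by the shift ratio.
    """
    from fractions import Fraction
    from scipy.signal import resample_poly

    x = np.asarray(x, dtype=np.float64)
    if n_semitones == 0:
        return x.copy()
    ratio = 2.0 ** (n_semitones / 12.0)
    stretched = time_stretch(x, rate=1.0 / ratio, n_fft=n_fft, hop=hop)
    frac = Fraction(1.0 / ratio).limit_denominator(1000)
    y = resample_poly(stretched, frac.numerator, frac.denominator)
    if y.size >= x.size:
        return y[: x.size]
    return np.concatenate([y, np.zeros(x.size - y.size)])


def dynamic_range_compress(x: np.ndarray, t_attack: float = 0.005,
                           t_release: float = 0.05, sample_rate: int = 22050,
                           threshold: float = 0.5) -> np.ndarray:
    """Attack/release envelope follower driving a limiter-style gain.

    The envelope obeys g(t) = a*g(t-1) + (1-a)*|x(t)| with the attack
    coefficient when |x(t)| exceeds g(t-1) and the release coefficient
    otherwise, a = exp(-1/(f_s * t)). The applied gain is
    min(1, threshold/g(t)) — signal below the threshold passes untouched.
    """
    if t_attack <= 0 or t_release <= 0:
        raise ValueError("time constants must be positive")
    x = np.asarray(x, dtype=np.float64)
    a_att = np.exp(-1.0 / (sample_rate * t_attack))
    a_rel = np.exp(-1.0 / (sample_rate * t_release))
    g = np.zeros(x.size)
    prev = 0.0
    ax = np.abs(x)
    for t in range(x.size):
        a = a_att if ax[t] > prev else a_rel
        prev = a * prev + (1 - a) * ax[t]
        g[t] = prev
    gain = np.where(g > threshold, threshold / np.maximum(g, 1e-12), 1.0)
    return x * gain


def attack_coefficient(t_const: float, sample_rate: float) -> float:
    """alpha = exp(-1 / (f_s * t)) for an attack or release time constant."""
    if t_const <= 0:
        raise ValueError("time constant must be positive")
    return float(np.exp(-1.0 / (sample_rate * t_const)))


# ---------------------------------------------------------------------------
# spectral-domain operators

def vtlp(spec: np.ndarray, alpha: float) -> np.ndarray:
    """Vocal tract length perturbation: warp the frequency axis f -> alpha*f.

    Output bin k is linearly interpolated from input position k/alpha, so
    spectral mass moves from f to alpha*f on the same grid (shape kept).
    """
    spec = np.asarray(spec, dtype=np.float64)
    n_bins = spec.shape[0]
    src = np.arange(n_bins) / alpha
    i0 = np.floor(src).astype(int)
    w = src - i0
    valid0 = i0 < n_bins
    valid1 = (i0 + 1) < n_bins
    s0 = np.where(valid0[:, None] if spec.ndim > 1 else valid0,
                  spec[np.clip(i0, 0, n_bins - 1)], 0.0)
    s1 = np.where(valid1[:, None] if spec.ndim > 1 else valid1,
                  spec[np.clip(i0 + 1, 0, n_bins - 1)], 0.0)
    wb = w[:, None] if spec.ndim > 1 else w
    return (1 - wb) * s0 + wb * s1


def formant_shift(mag: np.ndarray, beta: float) -> np.ndarray:
    """|X_shifted(k)| = |X(floor(k*beta))|, out-of-range sources read as 0."""
    mag = np.asarray(mag, dtype=np.float64)
    n_bins = mag.shape[0]
    src = np.floor(np.arange(n_bins) * beta).astype(int)
    valid = (src >= 0) & (src < n_bins)
    out = np.zeros_like(mag)
    out[valid] = mag[src[valid]]
    return out


def freq_dropout(spec: np.ndarray, p_dropout: float, rng: np.random.Generator) -> np.ndarray:
    """Multiply each cell by an independent Bernoulli(1-p) draw."""
    if not 0 <= p_dropout <= 1:
        raise ValueError("p_dropout must be in [0, 1]")
    spec = np.asarray(spec, dtype=np.float64)
    return spec * (rng.random(spec.shape) >= p_dropout)


def spec_augment(spec: np.ndarray, f_max: int, t_max: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Zero one frequency band (height <= f_max) and one time band (<= t_max)."""
    spec = np.asarray(spec, dtype=np.float64).copy()
    n_f, n_t = spec.shape
    if f_max > n_f:
        warnings.warn("frequency-mask cap exceeds matrix extent; clipping")
        f_max = n_f
    if t_max > n_t:
        warnings.warn("time-mask cap exceeds matrix extent; clipping")
        t_max = n_t
    df = int(rng.integers(0, f_max + 1))
    dt = int(rng.integers(0, t_max + 1))
    if df > 0:
        f0 = int(rng.integers(0, n_f - df + 1))
        spec[f0: f0 + df, :] = 0.0
    if dt > 0:
        t0 = int(rng.integers(0, n_t - dt + 1))
        spec[:, t0: t0 + dt] = 0.0
    return spec


# ---------------------------------------------------------------------------
# pairwise operators

@dataclass
class AugmentedSample:
    """An augmented waveform (or feature matrix) plus bookkeeping."""

    data: np.ndarray
    mixed_label: Optional[np.ndarray] = None
    applied_ops: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mixed_label is not None:
            self.mixed_label = np.asarray(self.mixed_label, dtype=np.float64)
            if abs(self.mixed_label.sum() - 1.0) > 1e-8:
                raise ValueError("mixed label vector must sum to 1")


def mixup(x_i: np.ndarray, x_j: np.ndarray, y_i: np.ndarray, y_j: np.ndarray,
          alpha: float = 0.4, rng: Optional[np.random.Generator] = None,
          lam: Optional[float] = None) -> AugmentedSample:
    """Convex combination of two samples, lambda ~ Beta(alpha, alpha)."""
    x_i, x_j = np.asarray(x_i, dtype=np.float64), np.asarray(x_j, dtype=np.float64)
    if x_i.shape != x_j.shape:
        raise ValueError("mixup inputs must have equal shapes")
    if lam is None:
        lam = float((rng or np.random.default_rng()).beta(alpha, alpha))
    y = lam * np.asarray(y_i, dtype=np.float64) + (1 - lam) * np.asarray(y_j, dtype=np.float64)
    return AugmentedSample(lam * x_i + (1 - lam) * x_j, y,
                           [("mixup", {"lambda": lam})])


def cutmix(x_i: np.ndarray, x_j: np.ndarray, y_i: np.ndarray, y_j: np.ndarray,
           coverage: float = 0.30, rng: Optional[np.random.Generator] = None) -> AugmentedSample:
    """One contiguous temporal mask takes samples from the partner clip.

    Labels are mixed by the realized coverage fraction.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie in (0, 1)")
    x_i, x_j = np.asarray(x_i, dtype=np.float64), np.asarray(x_j, dtype=np.float64)
    if x_i.shape != x_j.shape:
        raise ValueError("cutmix inputs must have equal shapes")
    rng = rng or np.random.default_rng()
    n = x_i.shape[0]
    m = int(round(coverage * n))
    start = int(rng.integers(0, n - m + 1)) if m < n else 0
    out = x_i.copy()
    out[start: start + m] = x_j[start: start + m]
    frac = m / n
    y = (1 - frac) * np.asarray(y_i, dtype=np.float64) + frac * np.asarray(y_j, dtype=np.float64)
    return AugmentedSample(out, y, [("cutmix", {"start": start, "length": m})])


# ---------------------------------------------------------------------------
# environment simulation

def room_reverb(x: np.ndarray, amplitude: float = 0.5, decay: float = 20.0,
                ir_duration: float = 0.3, sample_rate: int = 22050,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Convolve with a noise-excited exponentially decaying impulse response.

    h(t) = A * exp(-gamma t) * eta(t) with eta(0) = 1 (direct path) and
    eta(t>0) white noise; output truncated to the input length.
    """
    if amplitude <= 0 or decay <= 0:
        raise ValueError("amplitude and decay must be positive")
    from scipy.signal import fftconvolve

    x = np.asarray(x, dtype=np.float64)
    rng = rng or np.random.default_rng()
    n_h = max(1, int(round(ir_duration * sample_rate)))
    t = np.arange(n_h) / sample_rate
    eta = np.ones(n_h)
    if n_h > 1:
        eta[1:] = rng.standard_normal(n_h - 1)
    h = amplitude * np.exp(-decay * t) * eta
    return fftconvolve(x, h)[: x.size]


def colored_noise(x: np.ndarray, color: str = "white", sigma: float = 0.005,
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Add spectrally shaped noise with target standard deviation sigma.

    PSD slopes: white 0, pink -10, brown -20 dB per decade (amplitude
    shaping 1, 1/sqrt(f), 1/f on the rFFT of a white draw).
    """
    exponents = {"white": 0.0, "pink": 0.5, "brown": 1.0}
    if color not in exponents:
        raise ValueError(f"unknown noise color {color!r}")
    x = np.asarray(x, dtype=np.float64)
    if sigma == 0:
        return x.copy()
    rng = rng or np.random.default_rng()
    white = rng.standard_normal(x.size)
    if exponents[color] == 0:
        noise = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(x.size)
        shaping = np.zeros_like(f)
        shaping[1:] = f[1:] ** (-exponents[color])
        noise = np.fft.irfft(spec * shaping, n=x.size)
    noise = noise / max(noise.std(), 1e-300) * sigma
    return x + noise


# ---------------------------------------------------------------------------
# policy layer

@dataclass
class AugmentOp:
    """A named operator with a base probability and scalable parameter ranges.

    ``params`` maps parameter name -> (low, high, neutral); intensity
    scaling moves the bounds toward/away from the neutral value.
    """

    name: str
    domain: str  # {"waveform", "spectrogram", "pairwise"}
    base_probability: float = 0.5
    params: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.base_probability <= 1:
            raise ValueError("base probability must be in [0, 1]")

    def scaled_params(self, factor: float) -> dict[str, tuple[float, float]]:
        return {
            key: (neutral + factor * (lo - neutral), neutral + factor * (hi - neutral))
            for key, (lo, hi, neutral) in self.params.items()
        }


DEFAULT_OPS: list[AugmentOp] = [
    AugmentOp("time_stretch", "waveform", 0.5, {"rate": (0.8, 1.2, 1.0)}),
    AugmentOp("pitch_shift", "waveform", 0.5, {"n_semitones": (-2.0, 2.0, 0.0)}),
    AugmentOp("dynamic_range_compress", "waveform", 0.5,
              {"t_attack": (0.001, 0.01, 0.005), "t_release": (0.01, 0.1, 0.05)}),
    AugmentOp("room_reverb", "waveform", 0.5,
              {"amplitude": (0.2, 0.8, 0.5), "decay": (5.0, 40.0, 20.0)}),
    AugmentOp("colored_noise", "waveform", 0.5, {"sigma": (0.001, 0.01, 0.0)}),
    AugmentOp("vtlp", "spectrogram", 0.5, {"alpha": (0.85, 1.15, 1.0)}),
    AugmentOp("formant_shift", "spectrogram", 0.5, {"beta": (0.9, 1.1, 1.0)}),
    AugmentOp("freq_dropout", "spectrogram", 0.5, {"p_dropout": (0.05, 0.15, 0.0)}),
    AugmentOp("spec_augment", "spectrogram", 0.5, {}),
    AugmentOp("mixup", "pairwise", 0.5, {"alpha": (0.4, 0.4, 0.4)}),
    AugmentOp("cutmix", "pairwise", 0.5, {"coverage": (0.30, 0.30, 0.0)}),
]


_INTENSITY_TABLE = {
    "light": ((1, 2), 0.5),
    "medium": ((2, 4), 1.0),
    "heavy": ((3, 6), 1.5),
}


@dataclass
class IntensityPolicy:
    """Light / medium / heavy augmentation schedule."""

    level: str = "medium"

    def __post_init__(self) -> None:
        if self.level not in _INTENSITY_TABLE:
            raise ValueError(f"unknown intensity level {self.level!r}")

    @property
    def op_count_range(self) -> tuple[int, int]:
        return _INTENSITY_TABLE[self.level][0]

    @property
    def scale_factor(self) -> float:
        return _INTENSITY_TABLE[self.level][1]


def sample_policy(ops: Sequence[AugmentOp], policy: IntensityPolicy,
                  rng: np.random.Generator) -> list[tuple[AugmentOp, dict[str, float]]]:
    """Draw an ordered operator list with concrete, intensity-scaled parameters.

    Selection probability is proportional to clip(p_i * scale_factor, 0, 1);
    pairwise operators (mixup/cutmix) are ordered last since they need a
    partner sample.
    """
    if not ops:
        raise ValueError("operator list must be non-empty")
    lo_n, hi_n = policy.op_count_range
    k = min(int(rng.integers(lo_n, hi_n + 1)), len(ops))
    weights = np.clip([op.base_probability * policy.scale_factor for op in ops], 0.0, 1.0)
    if weights.sum() == 0:
        weights = np.ones(len(ops))
    probs = weights / weights.sum()
    chosen = rng.choice(len(ops), size=k, replace=False, p=probs)
    selected = [ops[i] for i in chosen]
    selected.sort(key=lambda op: op.domain == "pairwise")  # pairwise last, order kept
    drawn = []
    for op in selected:
        params = {name: float(rng.uniform(lo, hi)) if hi > lo else float(lo)
                  for name, (lo, hi) in op.scaled_params(policy.scale_factor).items()}
        drawn.append((op, params))
    return drawn


def apply_waveform_ops(x: np.ndarray, drawn: Sequence[tuple[AugmentOp, dict]],
                       rng: np.random.Generator, sample_rate: int = 22050,
                       partner: Optional[tuple[np.ndarray, np.ndarray]] = None,
                       label: Optional[np.ndarray] = None) -> AugmentedSample:
    """Run the waveform/pairwise portion of a drawn policy on one clip.

    ``partner`` provides the (waveform, one-hot label) pair required by
    mixup/cutmix; those ops are skipped if it is absent. The output is
    re-standardized to the input length.
    """
    from .preprocess import standardize_duration

    y = None if label is None else np.asarray(label, dtype=np.float64)
    n = x.size
    out = np.asarray(x, dtype=np.float64).copy()
    applied = []
    for op, params in drawn:
        if op.domain == "waveform":
            if op.name == "time_stretch":
                out = time_stretch(out, params["rate"])
            elif op.name == "pitch_shift":
                out = pitch_shift(out, params["n_semitones"], sample_rate)
            elif op.name == "dynamic_range_compress":
                out = dynamic_range_compress(out, params["t_attack"], params["t_release"], sample_rate)
            elif op.name == "room_reverb":
                out = room_reverb(out, params["amplitude"], params["decay"],
                                  sample_rate=sample_rate, rng=rng)
            elif op.name == "colored_noise":
                color = ["white", "pink", "brown"][int(rng.integers(0, 3))]
                out = colored_noise(out, color, params["sigma"], rng)
            out = standardize_duration(out, n)
            applied.append((op.name, params))
        elif op.domain == "pairwise" and partner is not None and y is not None:
            px, py = partner
            px = standardize_duration(np.asarray(px, dtype=np.float64), n)
            if op.name == "mixup":
                mixed = mixup(out, px, y, py, alpha=params.get("alpha", 0.4), rng=rng)
            else:
                mixed = cutmix(out, px, y, py, coverage=params.get("coverage", 0.30), rng=rng)
            out, y = mixed.data, mixed.mixed_label
            applied.extend(mixed.applied_ops)
    return AugmentedSample(out, y, applied)


def apply_spectrogram_ops(spec: np.ndarray, drawn: Sequence[tuple[AugmentOp, dict]],
                          rng: np.random.Generator, kind: str = "melspec") -> np.ndarray:
    """Run the spectrogram portion of a drawn policy on one feature matrix."""
    caps = {"mfcc": (30, 40), "melspec": (15, 25), "wavelet": (15, 25)}
    out = np.asarray(spec, dtype=np.float64)
    for op, params in drawn:
        if op.domain != "spectrogram":
            continue
        if op.name == "vtlp":
            out = vtlp(out, params["alpha"])
        elif op.name == "formant_shift":
            out = formant_shift(out, params["beta"])
        elif op.name == "freq_dropout":
            out = freq_dropout(out, params["p_dropout"], rng)
        elif op.name == "spec_augment":
            f_cap, t_cap = caps.get(kind, (15, 25))
            out = spec_augment(out, f_cap, t_cap, rng)
    return out
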