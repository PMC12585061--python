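"""Gradient-weighted class activation mapping over the CNN streams.

For a chosen stream and target class, the gradient of the class score
with respect to the stream's final convolutional map is spatially
averaged into per-channel weights; the weighted channel sum is rectified
and bilinearly upsampled to the stream's input feature-matrix extent,
then peak-normalized. The result localizes which time-frequency regions
drove the class score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .model import RespiratoryModel

__all__ = ["GradCamMap", "grad_cam", "band_mass"]

_STREAM_INPUT = {"mfcc": "x_mfcc", "wavelet": "x_wav", "melspec": "x_mel"}


@dataclass
class GradCamMap:
    heatmap: np.ndarray      # (rows, frames), values in [0, 1]
    target_class: int
    stream: str


def grad_cam(model: RespiratoryModel, x_mfcc: np.ndarray, x_wav: np.ndarray,
             x_mel: np.ndarray, target_class: int, stream: str) -> GradCamMap:
    """Heatmap for one sample (each input shaped (1, rows, frames, 1))."""
    if stream not in _STREAM_INPUT:
        raise ValueError(f"unknown stream {stream!r}")
    n_classes = model.config.fusion.num_classes
    if not 0 <= target_class < n_classes:
        raise ValueError(f"class index {target_class} outside [0, {n_classes})")
    was_training = model.training
    model.eval()
    out = model(x_mfcc, x_wav, x_mel)
    score = out.logits[0, target_class]
    score.backward()
    fmap = out.stream_activations[stream]
    acts = fmap.data[0]                      # (C, H', W')
    grads = fmap.grad[0]
    weights = grads.mean(axis=(1, 2))        # spatial mean per channel
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    target_shape = {"mfcc": x_mfcc, "wavelet": x_wav, "melspec": x_mel}[stream].shape[1:3]
    cam = zoom(cam, (target_shape[0] / cam.shape[0], target_shape[1] / cam.shape[1]),
               order=1, grid_mode=True, mode="grid-constant")
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    model.zero_grad()
    if was_training:
        model.train()
    return GradCamMap(heatmap=cam, target_class=target_class, stream=stream)


def band_mass(cam: GradCamMap, row_range: tuple[int, int]) -> float:
    """Fraction of heatmap mass inside a row (frequency-band) interval."""
    total = cam.heatmap.sum()
    if total == 0:
        return 0.0
    lo, hi = row_range
    return float(cam.heatmap[lo:hi].sum() / total)


def mel_rows_for_band(band_hz: tuple[float, float], n_mels: int, sample_rate: int,
                      f_min: float = 0.0, f_max: float | None = None) -> tuple[int, int]:
    """Mel-spectrogram row interval whose filter centers fall inside a band."""
    from .features import filterbank_centers

    centers = filterbank_centers(n_mels, sample_rate, f_min, f_max)
    inside = np.flatnonzero((centers >= band_hz[0]) & (centers <= band_hz[1]))
    if inside.size == 0:
        nearest = int(np.argmin(np.abs(centers - np.mean(band_hz))))
        return nearest, nearest + 1
    return int(inside[0]), int(inside[-1] + 1)
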