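"""Triple-stream CNN with discriminative-transformer fusion.

Three parallel convolutional streams (16/32/64 filters, 3x3 kernels,
Conv -> ReLU -> BatchNorm -> MaxPool per block) process the MFCC, wavelet
and mel-spectrogram matrices. A transformer encoder consumes an acoustic
embedding of the mel spectrogram (a learnable frequency-axis convolution,
projected to the hidden size, pooled to the encoder sequence length, plus
a learnable sinusoidal temporal embedding). Cross-modal attention couples
the pooled CNN sequence with the encoder output; a per-head learned scalar
``lambda_acoustic`` rescales the acoustic component of the attention
compatibility (an additive constant inside the softmax would cancel, so
the scalar multiplies the acoustic-key term instead). Class-attention
fusion gates acoustic vs. contextual features per class, and a 256-unit
head with dropout produces the logits.

Two presets exist: ``paper`` (hidden 768, 12 layers, 8 heads) mirrors the
full-scale configuration; ``tiny`` (hidden 32, 2 layers, 2 heads) runs the
identical graph at desk scale and is what all training-dependent tests use.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor, Parameter, Module, Dense, relu, softmax, concatenate

__all__ = [
    "StreamConfig", "EncoderConfig", "FusionConfig", "ModelConfig", "ModelOutput",
    "ConvBlock", "StreamCNN", "AcousticEmbedding", "TemporalEmbedding",
    "temporal_align_matrix", "temporal_align", "CrossModalAttention",
    "ClassFusion", "RespiratoryModel", "build_model",
]


@dataclass
class StreamConfig:
    filters: tuple[int, int, int] = (16, 32, 64)
    kernel: int = 3

    def __post_init__(self) -> None:
        if len(self.filters) != 3 or list(self.filters) != sorted(self.filters):
            raise ValueError("expect three increasing filter counts")


@dataclass
class EncoderConfig:
    hidden: int = 768
    layers: int = 12
    heads: int = 8
    seq_len: int = 128
    embed_channels: int = 8     # acoustic-embedding output channels C
    embed_freq_extent: int = 16  # kernel frequency extent F
    ln_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.hidden % self.heads:
            raise ValueError("hidden size must be divisible by the head count")

    @property
    def head_dim(self) -> int:
        return self.hidden // self.heads

    @property
    def concat_dim(self) -> int:
        return 2 * self.hidden


@dataclass
class FusionConfig:
    num_classes: int = 5
    intermediate_dim: int = 256
    dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class ModelConfig:
    stream: StreamConfig = field(default_factory=StreamConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    preset: str = "paper"
    seed: int = 0

    @classmethod
    def tiny(cls, num_classes: int = 5, seed: int = 0) -> "ModelConfig":
        return cls(
            encoder=EncoderConfig(hidden=32, layers=2, heads=2, seq_len=16,
                                  embed_channels=4, embed_freq_extent=8),
            fusion=FusionConfig(num_classes=num_classes),
            preset="tiny", seed=seed)

    @classmethod
    def paper(cls, num_classes: int = 5, seed: int = 0) -> "ModelConfig":
        return cls(fusion=FusionConfig(num_classes=num_classes), preset="paper", seed=seed)


@dataclass
class ModelOutput:
    logits: Tensor                      # (B, C)
    class_attention: np.ndarray         # (B, C), rows on the simplex
    confidence: np.ndarray              # (B,), max softmax probability
    probabilities: np.ndarray           # (B, C)
    stream_activations: dict[str, Tensor]  # final conv map per stream


class ConvBlock(Module):
    """Conv3x3 (same) -> ReLU -> BatchNorm -> MaxPool 2x2/2."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng, dtype=np.float64):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, kernel, rng, dtype=dtype)
        self.bn = nn.BatchNorm2d(c_out, dtype=dtype)
        self.pool = nn.MaxPool2d(2, 2)

    def __call__(self, x: Tensor) -> Tensor:
        return self.pool(self.bn(relu(self.conv(x))))


class StreamCNN(Module):
    """One dedicated stream: three conv blocks; exposes the final conv map."""

    def __init__(self, cfg: StreamConfig, rng, dtype=np.float64):
        super().__init__()
        f1, f2, f3 = cfg.filters
        self.blocks = [
            ConvBlock(1, f1, cfg.kernel, rng, dtype),
            ConvBlock(f1, f2, cfg.kernel, rng, dtype),
            ConvBlock(f2, f3, cfg.kernel, rng, dtype),
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x  # (B, 64, H', W') final conv map

    def forward_flat(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (flattened output O_i, final conv map)."""
        fmap = self(x)
        b = fmap.shape[0]
        return fmap.transpose(0, 2, 3, 1).reshape(b, -1), fmap


class AcousticEmbedding(Module):
    """Learnable frequency-axis convolution (kernel F x 1, C channels).

    Valid along frequency, so the time extent is preserved; the default
    kernel bank spans 16 frequency rows.
    """

    def __init__(self, freq_extent: int, channels: int, rng, dtype=np.float64):
        super().__init__()
        if freq_extent < 1 or channels < 1:
            raise ValueError("kernel extent and channel count must be positive")
        std = float(np.sqrt(1.0 / freq_extent))
        self.kernel = Parameter(rng.normal(0, std, (channels, freq_extent)).astype(dtype))

    def __call__(self, x: Tensor) -> Tensor:
        """(B, 1, F, T) -> (B, C, F - extent + 1, T)."""
        c, f_ext = self.kernel.shape
        n_freq = x.shape[2]
        if f_ext > n_freq:
            raise ValueError("kernel frequency extent exceeds input frequency extent")
        terms = []
        for u in range(f_ext):
            sl = x[:, :, u: u + n_freq - f_ext + 1, :]  # (B, 1, F', T)
            terms.append(sl * self.kernel[:, u].reshape(1, c, 1, 1))
        out = terms[0]
        for t in terms[1:]:
            out = out + t
        return out


class TemporalEmbedding(Module):
    """E(t) = W_t sin(omega t) + b_t with learnable frequencies omega."""

    def __init__(self, hidden: int, n_components: Optional[int] = None,
                 rng=None, dtype=np.float64):
        super().__init__()
        d = n_components or hidden
        rng = rng or np.random.default_rng(0)
        # geometric frequency ladder, standard positional-encoding style
        self.omega = Parameter((1.0 / 10000 ** (np.arange(d) / d)).astype(dtype))
        self.w_t = Parameter(nn.trunc_normal((d, hidden), rng, dtype=dtype))
        self.b_t = Parameter(np.zeros(hidden, dtype=dtype))

    def __call__(self, positions: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(positions, dtype=self.w_t.data.dtype).reshape(-1, 1))
        phases = (t * self.omega.reshape(1, -1)).sin()  # (L, D)
        return phases @ self.w_t + self.b_t              # (L, hidden)


def temporal_align_matrix(length: int, seq_len: int, dtype=np.float64) -> np.ndarray:
    """Area-overlap average-pooling matrix (seq_len x length).

    Each output position averages the input over the interval
    [i L / L_seq, (i+1) L / L_seq) with fractional-overlap weights, so the
    global mean is conserved exactly and length == seq_len gives identity.
    """
    if length < 1 or seq_len < 1:
        raise ValueError("lengths must be positive")
    if length == seq_len:
        return np.eye(length, dtype=dtype)
    p = np.zeros((seq_len, length), dtype=dtype)
    width = length / seq_len
    for i in range(seq_len):
        lo, hi = i * width, (i + 1) * width
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, length)):
            overlap = min(hi, j + 1) - max(lo, j)
            if overlap > 0:
                p[i, j] = overlap / width
    return p


def temporal_align(seq: Tensor, seq_len: int) -> Tensor:
    """Adaptive average pooling of (B, L, H) sequences to (B, seq_len, H)."""
    length = seq.shape[1]
    if length < 1:
        raise ValueError("empty sequence")
    p = temporal_align_matrix(length, seq_len, dtype=seq.data.dtype)
    return Tensor(p) @ seq


class EncoderLayer(Module):
    """Pre-built transformer block: MHSA + FFN, post-norm residuals."""

    def __init__(self, cfg: EncoderConfig, rng, dtype=np.float64):
        super().__init__()
        h = cfg.hidden
        self.heads, self.head_dim = cfg.heads, cfg.head_dim
        self.wq = Dense(h, h, rng, dtype=dtype)
        self.wk = Dense(h, h, rng, dtype=dtype)
        self.wv = Dense(h, h, rng, dtype=dtype)
        self.wo = Dense(h, h, rng, dtype=dtype)
        self.ln1 = nn.LayerNorm(h, cfg.ln_eps, dtype=dtype)
        self.ln2 = nn.LayerNorm(h, cfg.ln_eps, dtype=dtype)
        self.ff1 = Dense(h, 4 * h, rng, dtype=dtype)
        self.ff2 = Dense(4 * h, h, rng, dtype=dtype)

    def _split(self, x: Tensor) -> Tensor:
        b, l, _ = x.shape
        return x.reshape(b, l, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        b, l, h = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        attn = softmax(logits, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, l, h)
        x = self.ln1(x + self.wo(ctx))
        return self.ln2(x + self.ff2(relu(self.ff1(x))))


class CrossModalAttention(Module):
    """Attention over feature-wise concatenated acoustic + encoder tokens.

    Per head, queries/keys/values are projected from the 2*hidden token
    [h_aligned_p ; h_encoder_p]. The learned per-head scalar
    ``lambda_acoustic`` (initialized to 0) rescales the acoustic half of
    the key compatibility:

        A_k = softmax((Q K_enc^T + (1 + lambda_k) Q K_ac^T) / sqrt(d_k))

    so lambda modulates how strongly acoustic content drives attention
    while leaving the softmax normalization intact.
    """

    def __init__(self, cfg: EncoderConfig, rng, dtype=np.float64):
        super().__init__()
        h, two_h = cfg.hidden, cfg.concat_dim
        self.heads, self.head_dim = cfg.heads, cfg.head_dim
        self.wq = Dense(two_h, h, rng, dtype=dtype)
        self.wk_ac = Dense(h, h, rng, dtype=dtype)
        self.wk_enc = Dense(h, h, rng, dtype=dtype)
        self.wv = Dense(two_h, h, rng, dtype=dtype)
        self.lambda_acoustic = Parameter(np.zeros(cfg.heads, dtype=dtype))

    def attention_weights(self, h_aligned: Tensor, h_encoder: Tensor) -> Tensor:
        z = concatenate([h_aligned, h_encoder], axis=-1)
        b, l, _ = z.shape

        def split(x):
            return x.reshape(b, l, self.heads, self.head_dim).transpose(0, 2, 1, 3)

        q = split(self.wq(z))
        k_ac, k_enc = split(self.wk_ac(h_aligned)), split(self.wk_enc(h_encoder))
        scale = 1.0 / np.sqrt(self.head_dim)
        lam = self.lambda_acoustic.reshape(1, self.heads, 1, 1)
        logits = (q @ k_enc.transpose(0, 1, 3, 2)
                  + (1.0 + lam) * (q @ k_ac.transpose(0, 1, 3, 2))) * scale
        return softmax(logits, axis=-1)

    def __call__(self, h_aligned: Tensor, h_encoder: Tensor) -> Tensor:
        z = concatenate([h_aligned, h_encoder], axis=-1)
        b, l, _ = z.shape
        attn = self.attention_weights(h_aligned, h_encoder)
        v = self.wv(z).reshape(b, l, self.heads, self.head_dim).transpose(0, 2, 1, 3)
        return (attn @ v).transpose(0, 2, 1, 3).reshape(b, l, self.heads * self.head_dim)


class ClassFusion(Module):
    """Class-attention gating of acoustic vs. contextual vectors.

    alpha = softmax(W_a [ha; hx] + b_a) over classes;
    h_class(c) = W_c [alpha_c ha ; (1 - alpha_c) hx];
    h_final = LayerNorm(sum_c h_class(c)).
    """

    def __init__(self, hidden: int, num_classes: int, rng, ln_eps: float = 1e-6,
                 dtype=np.float64):
        super().__init__()
        self.num_classes = num_classes
        self.w_alpha = Dense(2 * hidden, num_classes, rng, dtype=dtype)
        self.w_class = [Parameter(nn.trunc_normal((2 * hidden, hidden), rng, dtype=dtype))
                        for _ in range(num_classes)]
        self.ln = nn.LayerNorm(hidden, ln_eps, dtype=dtype)

    def __call__(self, ha: Tensor, hx: Tensor) -> tuple[Tensor, Tensor]:
        alpha = softmax(self.w_alpha(concatenate([ha, hx], axis=-1)), axis=-1)  # (B, C)
        total = None
        for c in range(self.num_classes):
            a_c = alpha[:, c].reshape(-1, 1)
            gated = concatenate([a_c * ha, (1.0 - a_c) * hx], axis=-1)
            h_c = gated @ self.w_class[c]
            total = h_c if total is None else total + h_c
        return self.ln(total), alpha


class RespiratoryModel(Module):
    """The full triple-stream + transformer fusion classifier."""

    def __init__(self, config: ModelConfig, dtype=np.float64):
        super().__init__()
        self.config = config
        enc, fus = config.encoder, config.fusion
        rng = np.random.default_rng(config.seed)
        self.dtype = dtype
        self.streams = {
            "mfcc": StreamCNN(config.stream, rng, dtype),
            "wavelet": StreamCNN(config.stream, rng, dtype),
            "melspec": StreamCNN(config.stream, rng, dtype),
        }
        self.acoustic_embed = AcousticEmbedding(
            enc.embed_freq_extent, enc.embed_channels, rng, dtype)
        self.embed_proj: Optional[Dense] = None  # lazily sized from input
        self.temporal_embed = TemporalEmbedding(enc.hidden, rng=rng, dtype=dtype)
        self.encoder_layers = [EncoderLayer(enc, rng, dtype) for _ in range(enc.layers)]
        self.stream_proj: dict[str, Dense] = {}
        self.cross_attention = CrossModalAttention(enc, rng, dtype)
        self.fusion = ClassFusion(enc.hidden, fus.num_classes, rng, enc.ln_eps, dtype)
        self.head1 = Dense(enc.hidden, fus.intermediate_dim, rng, dtype=dtype)
        self.dropout = nn.Dropout(fus.dropout, np.random.default_rng(config.seed + 1))
        self.head2 = Dense(fus.intermediate_dim, fus.num_classes, rng, dtype=dtype)
        self._lazy_rng = np.random.default_rng(config.seed + 2)

    # -- lazily-created projections (input frame counts vary with duration) --
    def _get_proj(self, name: str, d_in: int) -> Dense:
        proj = self.stream_proj.get(name)
        if proj is None or proj.weight.shape[0] != d_in:
            if proj is not None:
                raise ValueError(f"stream {name}: feature width changed across calls")
            proj = Dense(d_in, self.config.encoder.hidden, self._lazy_rng, dtype=self.dtype)
            self.stream_proj[name] = proj
        return proj

    def _stream_sequence(self, name: str, fmap: Tensor) -> Tensor:
        """Final conv map (B, C, H', W') -> projected sequence (B, L_seq, hidden)."""
        b, c, hh, ww = fmap.shape
        seq = fmap.transpose(0, 3, 1, 2).reshape(b, ww, c * hh)
        proj = self._get_proj(name, c * hh)
        return temporal_align(proj(seq), self.config.encoder.seq_len)

    def encoder_input(self, x_mel: Tensor) -> Tensor:
        """Acoustic embedding of the mel matrix -> encoder token sequence."""
        emb = self.acoustic_embed(x_mel)  # (B, C, F', T)
        b, c, f_, t_ = emb.shape
        seq = emb.transpose(0, 3, 1, 2).reshape(b, t_, c * f_)
        if self.embed_proj is None or self.embed_proj.weight.shape[0] != c * f_:
            if self.embed_proj is not None:
                raise ValueError("mel feature extent changed across calls")
            self.embed_proj = Dense(c * f_, self.config.encoder.hidden,
                                    self._lazy_rng, dtype=self.dtype)
        seq = temporal_align(self.embed_proj(seq), self.config.encoder.seq_len)
        pos = self.temporal_embed(np.arange(self.config.encoder.seq_len))
        return seq + pos

    def __call__(self, x_mfcc, x_wav, x_mel) -> ModelOutput:
        inputs = {"mfcc": x_mfcc, "wavelet": x_wav, "melspec": x_mel}
        tensors = {}
        for name, arr in inputs.items():
            arr = arr.data if isinstance(arr, Tensor) else np.asarray(arr, dtype=self.dtype)
            if arr.ndim != 4 or arr.shape[-1] != 1:
                raise ValueError(f"{name}: expected (B, rows, frames, 1), got {arr.shape}")
            tensors[name] = Tensor(arr.astype(self.dtype, copy=False)
                                   .transpose(0, 3, 1, 2))  # NCHW

        fmaps = {name: self.streams[name](x) for name, x in tensors.items()}
        seqs = [self._stream_sequence(name, fmap) for name, fmap in fmaps.items()]
        h_aligned = (seqs[0] + seqs[1] + seqs[2]) * (1.0 / 3.0)

        h_enc = self.encoder_input(tensors["melspec"])
        for layer in self.encoder_layers:
            h_enc = layer(h_enc)

        attended = self.cross_attention(h_aligned, h_enc)
        ha = h_aligned.mean(axis=1)
        hx = attended.mean(axis=1)
        h_final, alpha = self.fusion(ha, hx)
        logits = self.head2(self.dropout(relu(self.head1(h_final))))

        probs = _np_softmax(logits.data)
        return ModelOutput(
            logits=logits,
            class_attention=alpha.data.copy(),
            confidence=probs.max(axis=1),
            probabilities=probs,
            stream_activations=fmaps,
        )

    # -- persistence --------------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        np.savez(os.fspath(path), **self.state_dict())
        with open(os.fspath(path) + ".json", "w") as fh:
            json.dump({"preset": self.config.preset,
                       "num_classes": self.config.fusion.num_classes,
                       "seed": self.config.seed}, fh)


def _np_softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def build_model(preset: str = "tiny", num_classes: int = 5, seed: int = 0,
                dtype=None) -> RespiratoryModel:
    if preset == "tiny":
        cfg = ModelConfig.tiny(num_classes, seed)
        return RespiratoryModel(cfg, dtype or np.float64)
    if preset == "paper":
        cfg = ModelConfig.paper(num_classes, seed)
        return RespiratoryModel(cfg, dtype or np.float32)
    raise ValueError(f"unknown preset {preset!r}")
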