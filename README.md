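# lungsound

Automated classification of respiratory sounds (asthma, COPD, pneumonia,
bronchial conditions, healthy breathing) from auscultation recordings.
The package is aimed at researchers in biomedical acoustics who want a
fully inspectable, desk-scale implementation of a triple-stream
CNN–transformer fusion pipeline: every stage — from the waveform contract
to the explanation heatmaps — is ordinary numpy/scipy code that can be
unit-tested and rerun deterministically.

## The method

A recording is standardized to a mono waveform at f_s = 22,050 Hz with
peak normalization x_norm(t) = x(t) / max|x(t)| and a fixed duration
(6 s → SAMPLES = 132,300; shorter clips are tail-padded with zeros,
longer ones truncated). Three acoustic representations are computed on a
shared 259-frame grid (window N = 2048, hop H = 512, centered framing):

* **MFCC** (20 × 259): Hamming-windowed STFT → power spectrum
  P[k,m] = |STFT[k,m]|² → 40 triangular filters on the mel scale
  mel(f) = 2595·log₁₀(1 + f/700) → cepstra
  MFCC(p,m) = Σ_k log(S[k,m] + ε) · cos(πp(k+½)/40), 0 ≤ p < 20.
* **Wavelet** (20 × 259): 5-level Daubechies-1 decomposition; the six
  sub-bands (a₅, d₅…d₁) become per-frame mean-|·| envelopes interpolated
  to 20 rows, coarse to fine.
* **Log-mel spectrogram** (128 × 259): Hann window, 128 mel filters,
  X_mel = 10·log₁₀(S_mel + 1e−10).

Each stream feeds a dedicated CNN of three blocks
MaxPool(BN(ReLU(Conv3×3))) with 16/32/64 filters. A transformer encoder
(hidden 768, 12 layers, 8 heads at full scale; 32/2/2 in the `tiny`
preset every test runs on) consumes an acoustic embedding of the mel
spectrogram with a learnable sinusoidal temporal embedding
E(t) = W_t·sin(ωt) + b_t. Cross-modal attention couples the pooled CNN
sequence h_aligned with the encoder output, with a learned per-head
scalar λ rescaling the acoustic key compatibility; class-attention
fusion α = softmax(W_α[h_a; h_x]) gates acoustic vs. contextual features
per class, h_class^(c) = W_c[α_c h_a; (1−α_c) h_x], and
h_final = LayerNorm(Σ_c h_class^(c)) enters a 256-unit head with
dropout 0.3.

Around the model sit: a 17-operator augmentation pipeline with
light/medium/heavy intensity scheduling (time stretch, pitch shift,
compression, VTLP, formant shift, frequency dropout, mixup, cutmix,
reverb, colored noise, SpecAugment); Harmony Search with
Opposition-Based Learning (HMCR 0.9, PAR 0.3, HMS 30, opposites
h′ = x_min + x_max − h on stagnation) for hyperparameter search;
confusion-table metrics including per-class and multiclass Matthews
correlation; and Grad-CAM explanations over each CNN stream. A seeded
synthetic generator produces class-conditional recordings (asthmatic
wheeze 400–600 Hz, COPD 200–350 Hz, pneumonia crackles 300–800 Hz) so
the whole method runs without clinical data.

## Worked example

`examples/03_train_and_explain.py` trains the tiny preset on 32 short
synthetic clips of asthma vs. COPD — two classes that differ only in
where their wheeze energy sits — and then asks Grad-CAM which mel bands
drove the asthma decision:

```
training: 8 optimizer steps, accuracy 100.0%, MCC 1.000
Grad-CAM mass in mel rows (18, 30) (~350-650 Hz): 0.27 vs uniform share 0.09
-> the explanation localizes the asthma decision to the wheeze band
```

The model separates the classes perfectly within a handful of steps, and
the explanation concentrates about three times more heatmap mass in the
wheeze band than a uniform map would — the decision is made where the
pathology lives. The other examples cover feature extraction
(`01_features.py`), the augmentation policy (`02_augmentation.py`), the
optimizer on a convex benchmark (`04_harmony_search.py`), and the full
pipeline with artifact output (`05_full_pipeline.py`). A thin CLI wraps
the same functions: `lungsound simulate | features | augment | optimize
| run | model-summary`.

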