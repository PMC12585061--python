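# Methods

This note records the model, the numerical conventions, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal contract

All processing assumes mono audio at f_s = 22,050 Hz. Multi-channel
input is down-mixed by the arithmetic mean of channels; other sample
rates are converted by band-limited polyphase resampling
(`scipy.signal.resample_poly`) *before* feature extraction, because the
framing constants (N = 2048, H = 512) are only meaningful at 22,050 Hz.
Peak normalization divides by max|x| (all-zero input passes through
unchanged). Duration standardization is exact: identity at the target
length, tail zero-padding below it, leading-prefix truncation above it —
no random cropping, so the pipeline is deterministic. Clip duration is a
config field: 6 s is the default profile (132,300 samples, 259 frames);
a 4 s profile suits corpora distributed as 4-second windows; the test
suite and acceptance script use a 1.5 s desk-scale profile (33,075
samples, 65 frames) so that training-dependent properties run in
seconds. All feature and model code derives its shapes from the config;
nothing is hard-coded to 259 frames.

## Feature extraction

Framing is centered with reflect padding, giving 1 + ⌊L/H⌋ frames; this
is the only standard convention that yields 259 frames from 132,300
samples at hop 512 (uncentered framing gives 255). Windows are the
symmetric cosine forms w(n) = 0.54 − 0.46·cos(2πn/(N−1)) (Hamming, MFCC
path) and 0.5·(1 − cos(2πn/(N−1))) (Hann, mel path).

The mel scale is the HTK form mel(f) = 2595·log₁₀(1 + f/700) for both
the 40-filter (MFCC) and 128-filter (spectrogram) banks; filters are
triangular with centers equispaced in mel between 0 Hz and f_s/2 and no
area normalization. The cepstral transform is the literal cosine sum
Σ_{k=0}^{39} log(S_k + ε)·cos(πp(k+½)/40) with no orthonormal scaling —
the plain DCT-II kernel — and the log guard ε = 1e−10 matches the mel
spectrogram's (whose output is 10·log₁₀(S + 1e−10), hence an exact
−100 dB floor for silent input).

The wavelet stream uses PyWavelets' 5-level `db1` (Haar) analysis. The
arrangement of six sub-bands (a₅, d₅ … d₁) into a 20-row matrix is not
dictated by any formula, so this package defines it as: each sub-band is
reduced to one value per STFT frame by mean absolute pooling over
near-equal segments (linear interpolation when a deep sub-band is
shorter than the frame grid), and the six envelope rows are linearly
interpolated to 20 rows preserving coarse-to-fine order. The scheme is
deterministic, shape-exact for any clip duration, and keeps the
multi-resolution band ordering; it is a declared convention of this
implementation, not a canonical one.

## Augmentation

Waveform operators run before feature extraction and are followed by
re-standardization to the contract length; spectral operators (VTLP,
formant shift, frequency dropout, SpecAugment) run on the extracted
matrices. Parameter ranges at unit intensity: stretch rate 0.8–1.2,
pitch shift ±2 semitones, VTLP warp 0.85–1.15, formant shift 0.9–1.1,
frequency dropout 0.05–0.15, mixup λ ~ Beta(0.4, 0.4), cutmix coverage
30 % (one contiguous temporal segment; label mixed by realized
coverage), noise σ 0.001–0.01 (white/pink/brown via FFT spectral shaping
1, 1/√f, 1/f), SpecAugment caps F = 30/T = 40 for MFCC and 15/25 for the
mel spectrogram. The intensity schedule draws 1–2 / 2–4 / 3–6 operators
at 0.5× / 1.0× / 1.5× parameter scaling for light/medium/heavy; scaling
moves each bound toward or away from the operator's neutral point (rate
1, shift 0, warp 1, probability 0 …), so light intensity genuinely means
smaller perturbations. Selection probability is clip(p_i · factor, 0, 1)
with all base probabilities defaulting to 0.5 (no per-operator weights
are prescribed anywhere, so a uniform prior is used). Pairwise operators
order last because they need a partner clip. Dynamic-range compression
completes the attack/release envelope recursion
(α = e^(−1/(f_s·t))) with a limiter-style gain min(1, threshold/g),
threshold 0.5 — the recursion alone defines no output. The reverb
impulse response is A·e^(−γt)·η(t) with η(0) = 1 (direct path) and a
0.3 s noise tail. All stochastic draws flow from one explicit
`numpy.random.Generator`; no global RNG state is touched.

Time stretch and pitch shift use a phase vocoder (magnitude
interpolation with phase accumulation at hop 512); pitch shift is a
stretch by 2^(−n/12) followed by polyphase resampling back to the input
length. Neutral parameters short-circuit to exact copies.

## Model

Each stream's CNN is three blocks of MaxPool₂ₓ₂(BN(ReLU(Conv3×3))) with
16/32/64 filters — batch norm deliberately sits *after* the activation,
matching the formula convention adopted here, though BN-before-ReLU is
more common. Convolutions use same padding; pooling floors odd extents.
Flattened stream outputs at the 6 s profile are 4,096-dimensional
(MFCC/wavelet) and 32,768-dimensional (mel).

The encoder input is built from the mel spectrogram: a learnable
frequency-axis convolution (valid along frequency, kernel extent 16,
8 channels at full scale), flattened per frame, projected to the hidden
size, pooled to the encoder sequence length, plus the learnable
sinusoidal temporal embedding E(t) = W_t·sin(ωt) + b_t (ω initialized as
a geometric frequency ladder). No token vocabulary exists anywhere; the
encoder consumes these continuous embeddings directly. Temporal pooling
uses area-overlap averaging, which is the identity when lengths match
and conserves the sequence mean exactly.

Cross-modal attention operates on tokens [h_aligned,p ; h_encoder,p]
(feature-wise concatenation, 2·hidden per position). A per-head additive
constant inside the softmax cancels algebraically, so the learned
acoustic-strength scalar enters multiplicatively instead:
A_k = softmax((Q K_enc^T + (1 + λ_k)·Q K_ac^T)/√d_k), where K_ac and
K_enc are the key projections of the acoustic and encoder halves. At
λ = 0 this is exactly standard attention over the concatenated features;
λ_k (initialized 0) modulates how strongly acoustic content drives the
compatibility without breaking row normalization. Class fusion pools
h_aligned and the attended sequence over time, computes class attention
α on the simplex, gates the two vectors per class with α_c and 1 − α_c,
sums the class branches and layer-normalizes (ε = 1e−6). The head is
dense(256) → ReLU → dropout(0.3) → dense(C).

Two presets share the graph: `paper` (hidden 768, 12 layers, 8 heads,
head dim 96, float32, encoder sequence length 128 — the length itself is
a free choice here since only "the encoder's sequence length" is
specified, and 128 keeps the full-scale forward pass tractable on a CPU)
and `tiny` (32/2/2, sequence length 16, float64). Initialization is
truncated normal (σ = 0.02, clipped at 2σ) for projections and He-normal
for conv kernels, all from the model seed. Stream projections are
created lazily on the first forward pass because their input width
depends on the clip duration; the training loop therefore runs one
probe forward before building the optimizer.

The network runs on `lungsound.nn`, a small tape-based reverse-mode
autodiff engine over numpy (elementwise ops, matmul, reductions,
same-padded conv via im2col, 2×2 max pooling, batch/layer norm,
dropout, AdamW). Gradients are retained at every graph node, which is
what Grad-CAM needs. Every primitive is finite-difference-checked in the
test suite.

## Training and evaluation

AdamW (β₁ = 0.9, β₂ = 0.999, weight decay 0.01) with gradient
accumulation: one optimizer step per 4 micro-batches of 8 (effective
batch 32) at the full-scale defaults, learning rate 1e−5. Early stopping
monitors validation loss with patience 10; the default schedule cuts the
learning rate by 0.1 after 5 stagnant epochs, with cosine decay
available by config. Loss is soft-target cross entropy, so mixup/cutmix
labels need no special casing. Desk-scale runs (tests, acceptance
script) use lr 1e−3 with no accumulation — at hidden size 32 and ~50
training clips the full-scale learning rate would simply not move.
Splitting is stratified 60/20/20 per class with largest-remainder
rounding (ties resolved toward train, then validation); classes with
fewer than 3 members are rejected by name.

Accuracy is trace/total of the confusion table ×100; precision, recall
and F1 are one-vs-rest percentages with zero-denominator cells defined
as 0 and flagged. The primary MCC is the macro average of per-class
binary coefficients; the covariance-form multiclass MCC is reported
alongside (the two differ, and which one a single printed "MCC" means is
ambiguous in general). Both agree exactly with scikit-learn on random
label sets in the tests.

Grad-CAM weights each final-conv-map channel by the spatial mean of
∂(class score)/∂(channel), rectifies the weighted sum, bilinearly
upsamples to the stream's feature extent and peak-normalizes. Heatmaps
are non-negative by construction and can be identically zero when every
weighted channel is negative — callers should treat a zero map as "no
positive evidence", which the band-mass statistic does (it returns 0).

## Hyperparameter search

HS-OBL keeps a memory of HMS = 30 candidate vectors. Per iteration it
improvises one candidate per memory slot: each dimension copies a value
from a random memory member with probability HMCR (then perturbs it
within a bandwidth with probability PAR, clipped to bounds) or redraws
uniformly (log-uniformly for log-scaled dimensions). A strictly better
candidate replaces the worst member. HMCR and PAR decay linearly
(0.9 → 0.7, 0.3 → 0.1 over the run) and the pitch bandwidth decays
exponentially from 5 % to 0.1 % of each dimension's range — all three
schedules implement the same exploration-to-exploitation transition; a
fixed bandwidth measurably stalls refinement on convex benchmarks.
Opposition fires when the best fitness stagnates for 5 iterations: the
memory is reflected through the box center (h′ = x_min + x_max − h, an
involution with the midpoint fixed), reflections are evaluated, and the
best HMS of the union survive. Integer and categorical dimensions are
relaxed to continuous and rounded at evaluation time. For expensive
objectives (model training) `improvisations_per_iteration = 1`
restores a one-candidate-per-iteration budget; fitness for model tuning
is the scalarization w₁(1 − val_acc) + w₂·gap + w₃·time with default
weights (0.6, 0.3, 0.1) — the three components are prescribed, their
weights are this package's choice. A failing fitness evaluation is
recorded as +∞ with a warning and the run continues.

## Synthetic data

The generator emulates exactly the spectral geography the classifier is
supposed to exploit: an amplitude-modulated narrowband tone whose center
frequency random-walks inside the class's wheeze band (asthma 400–600
Hz, COPD 200–350 Hz, bronchial 300–450 Hz — the bronchial profile is an
invention of this package), Poisson-timed band-filtered damped impulses
(< 20 ms) for crackles (pneumonia, 300–800 Hz at 10 events/s), a
raised-cosine breath-cycle envelope (18 cycles/min, ~10 % jitter), and a
Gaussian noise floor (σ = 0.05) — then peak normalization. It does *not*
model airway physics, stethoscope coloration, heart sounds, or real
recording noise. Consequently, passing tests demonstrate that the
pipeline can learn and localize band-structured spectral evidence, not
that it reaches any particular accuracy on clinical recordings; results
on real corpora require real data. One practical interaction worth
knowing: because clips are peak-normalized, a class pair like
asthma-vs-healthy differs in noise-floor *level* as well as band
content, and a classifier may legitimately use either cue. The Grad-CAM
localization experiments therefore contrast asthma with COPD, where the
band position is the only discriminative feature.

## Desk-scale profile and known limitations

Training-dependent tests and the acceptance script use 1.5 s clips,
12–16 clips per class, the tiny preset, and early exit once the target
validation accuracy is reached — the same graph and code paths as the
full-scale configuration at a fraction of the arithmetic. The full-scale
preset is exercised once per suite as a shape/contract audit (forward
pass only). Known limitations: the numpy engine is single-threaded
BLAS-bound and unsuitable for full-scale training; no pretrained encoder
weights are loadable (the checkpoint format of the reference
discriminator family is out of scope); the wavelet-matrix arrangement
and several augmentation completions (compressor gain law, reverb tail,
noise synthesis) are this package's own conventions where no formula
pinned them down.
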