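"""Draw an intensity-scheduled augmentation policy and apply it.

Shows which operators were sampled under the 'medium' intensity level,
the concrete parameters drawn for each, and that a 440 Hz tone keeps
(or shifts) its dominant frequency as each operator promises.
"""

import numpy as np

from lungsound.augment import (DEFAULT_OPS, IntensityPolicy,
                               apply_waveform_ops, pitch_shift, sample_policy,
                               time_stretch)

fs = 22050
tone = np.sin(2 * np.pi * 440 * np.arange(2 * fs) / fs)


def peak(x):
    return np.fft.rfftfreq(x.size, 1 / fs)[np.abs(np.fft.rfft(x)).argmax()]


print(f"input: 440 Hz tone, dominant frequency {peak(tone):.1f} Hz")
print(f"time_stretch rate=1.2  -> {peak(time_stretch(tone, 1.2)):.1f} Hz (pitch kept)")
print(f"pitch_shift  n=+2      -> {peak(pitch_shift(tone, 2)):.1f} Hz "
      f"(expected {440 * 2 ** (2 / 12):.1f})")

rng = np.random.default_rng(4)
drawn = sample_policy(DEFAULT_OPS, IntensityPolicy("medium"), rng)
print("\nmedium-intensity policy draw:")
for op, params in drawn:
    print(f"  {op.name:24s} {params}")
out = apply_waveform_ops(tone, drawn, rng, fs, label=np.array([1.0, 0.0]),
                         partner=(np.zeros_like(tone), np.array([0.0, 1.0])))
print(f"augmented clip: length {out.data.size} (re-standardized), "
      f"label {np.round(out.mixed_label, 3)}")
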