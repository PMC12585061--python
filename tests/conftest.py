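"""Shared fixtures: short-clip synthetic datasets and trained tiny models.

Training-dependent fixtures are session-scoped so the expensive work
(feature extraction + gradient descent) happens once. Desk-scale clips
are 1.5 s long, giving 65-frame feature matrices on the standard hop.
"""

import numpy as np
import pytest

from lungsound.features import FeatureBundle, FeatureConfig
from lungsound.model import build_model
from lungsound.pipeline import featurize_clips
from lungsound.synthdata import DEFAULT_PROFILES, SynthDatasetSpec, generate_clips
from lungsound.training import TrainConfig, evaluate_accuracy, train

SHORT_DURATION = 1.5  # seconds -> 33,075 samples -> 65 frames


@pytest.fixture(scope="session")
def feat_cfg():
    return FeatureConfig()


@pytest.fixture(scope="session")
def short_clip():
    """One deterministic synthetic asthma clip (1.5 s, peak-normalized)."""
    spec = SynthDatasetSpec(classes=[DEFAULT_PROFILES["asthma"]], per_class=1,
                            duration=SHORT_DURATION, seed=11)
    clips, _ = generate_clips(spec)
    return clips[0]


@pytest.fixture(scope="session")
def two_class_data():
    """32 clips, asthma vs COPD (the classes differ only in wheeze band)."""
    spec = SynthDatasetSpec(
        classes=[DEFAULT_PROFILES["asthma"], DEFAULT_PROFILES["copd"]],
        per_class=16, duration=SHORT_DURATION, seed=3)
    clips, labels = generate_clips(spec)
    names = sorted(set(labels))
    fb, targets = featurize_clips(clips, FeatureConfig(), labels, names)
    return {"clips": clips, "labels": labels, "names": names,
            "bundle": fb, "targets": targets}


@pytest.fixture(scope="session")
def trained_two_class(two_class_data):
    """Tiny model fitted to the 32-clip two-class set (stops at 100%)."""
    model = build_model("tiny", num_classes=2, seed=3)
    cfg = TrainConfig(lr=1e-3, base_batch=8, grad_accum=1, max_epochs=50,
                      patience=50, seed=3)
    history = train(model, two_class_data["bundle"], two_class_data["targets"],
                    two_class_data["bundle"], two_class_data["targets"], cfg,
                    stop_at_val_accuracy=1.0)
    accuracy = evaluate_accuracy(model, two_class_data["bundle"],
                                 two_class_data["targets"])
    return {"model": model, "history": history, "train_accuracy": accuracy}


def subset_bundle(fb: FeatureBundle, idx) -> FeatureBundle:
    return FeatureBundle(fb.x_mfcc[idx], fb.x_wav[idx], fb.x_mel[idx])
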