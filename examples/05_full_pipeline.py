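"""Run the whole pipeline in one call.

Simulates a 3-class dataset, extracts features, trains the tiny preset,
evaluates on the held-out split, and renders a Grad-CAM heatmap — all
artifacts land in one timestamped run directory.
"""

import json
import os

from lungsound.pipeline import RunConfig, run_pipeline
from lungsound.preprocess import PreprocessConfig
from lungsound.training import TrainConfig

config = RunConfig(
    preprocess=PreprocessConfig(duration=1.5),
    train=TrainConfig(lr=1e-3, base_batch=8, grad_accum=1, max_epochs=15,
                      patience=10, seed=0),
    classes=("asthma", "copd", "healthy"),
    per_class=10,
    seed=0,
    stop_at_val_accuracy=0.95,
)
run_dir = run_pipeline(config, out_root="scratch/runs")
print(f"run directory: {run_dir}")
with open(os.path.join(run_dir, "metrics.json")) as fh:
    report = json.load(fh)
print(f"test accuracy {report['accuracy']:.1f}%  "
      f"macro F1 {report['macro_f1']:.1f}%  MCC {report['mcc_macro']:.3f}")
print(f"artifacts: {sorted(os.listdir(run_dir))}")
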