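"""End-to-end pipeline: data -> preprocess -> augment -> features ->
optional hyperparameter search -> training -> evaluation -> explanation.

Every run writes its artifacts (config snapshot, metrics JSON, confusion
CSV, Grad-CAM heatmaps, JSON event log) under one timestamped directory,
and a single global seed fans out deterministically to every stage.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .augment import DEFAULT_OPS, IntensityPolicy, apply_waveform_ops, sample_policy
from .features import FeatureConfig, bundle
from .gradcam import grad_cam
from .hsobl import Dimension, HSConfig, SearchSpace, optimize
from .metrics import MetricsReport
from .model import build_model
from .preprocess import PreprocessConfig, RawRecording, load_manifest, standardize
from .synthdata import DEFAULT_PROFILES, SynthDatasetSpec, generate_clips
from .training import (TrainConfig, evaluate, evaluate_accuracy, one_hot,
                       stratified_split, train)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "featurize_clips",
           "augment_waveforms"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=lambda: PreprocessConfig(duration=1.5))
    features: FeatureConfig = field(default_factory=FeatureConfig)
    preset: str = "tiny"
    train: TrainConfig = field(default_factory=lambda: TrainConfig(lr=1e-3, max_epochs=30,
                                                                   patience=10))
    augment_level: Optional[str] = None   # None disables augmentation
    optimize_hyperparams: bool = False
    hs: HSConfig = field(default_factory=lambda: HSConfig(
        hms=4, max_iterations=3, improvisations_per_iteration=1))
    classes: tuple[str, ...] = ("asthma", "copd", "healthy")
    per_class: int = 20
    seed: int = 0
    manifest: Optional[str] = None        # real data instead of synthesis
    max_steps: Optional[int] = None
    stop_at_val_accuracy: Optional[float] = None

    def to_yaml_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess"] = {"target_rate": self.preprocess.target_rate,
                           "duration": self.preprocess.duration}
        return d


def featurize_clips(clips: np.ndarray, feat_cfg: FeatureConfig,
                    labels, class_names) -> tuple:
    """Waveform matrix (n, samples) -> (FeatureBundle, one-hot targets)."""
    per_clip = [extract_features_from_array(c, feat_cfg) for c in clips]
    fb = bundle(per_clip)
    return fb, one_hot(list(labels), list(class_names))


def extract_features_from_array(x: np.ndarray, cfg: FeatureConfig):
    from .features import mel_spectrogram, mfcc, wavelet_features
    return {"mfcc": mfcc(x, cfg), "wavelet": wavelet_features(x, cfg),
            "melspec": mel_spectrogram(x, cfg)}


def augment_waveforms(clips: np.ndarray, targets: np.ndarray, level: str,
                      rng: np.random.Generator, sample_rate: int) -> tuple[np.ndarray, np.ndarray]:
    """One augmented copy per clip under the intensity policy (waveform ops)."""
    policy = IntensityPolicy(level)
    out_x, out_y = [], []
    n = clips.shape[0]
    for i in range(n):
        drawn = sample_policy(DEFAULT_OPS, policy, rng)
        j = int(rng.integers(n))
        aug = apply_waveform_ops(clips[i], drawn, rng, sample_rate,
                                 partner=(clips[j], targets[j]), label=targets[i])
        out_x.append(aug.data)
        out_y.append(aug.mixed_label if aug.mixed_label is not None else targets[i])
    return np.stack(out_x), np.stack(out_y)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig, out_root: str | os.PathLike = "runs") -> str:
    """Execute the full pipeline; returns the run directory path."""
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2 ** 31)
    stamp = _dt.datetime.now().strftime("%Y%m%d-%H%M%S")
    run_dir = os.path.join(os.fspath(out_root), f"run-{stamp}-seed{config.seed}")
    os.makedirs(run_dir, exist_ok=True)
    events: list[dict] = []

    def log(stage: str, **info):
        events.append({"stage": stage, **info})

    with open(os.path.join(run_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_yaml_dict(), fh)

    # ---- data ------------------------------------------------------------
    @_stage("data")
    def load_data():
        pp = config.preprocess
        if config.manifest is not None:
            std = load_manifest(config.manifest, pp)
            clips = np.stack([c.samples for c in std])
            labels = [c.label for c in std]
        else:
            profiles = [DEFAULT_PROFILES[c] for c in config.classes]
            spec = SynthDatasetSpec(classes=profiles, per_class=config.per_class,
                                    duration=pp.duration, sample_rate=pp.target_rate,
                                    seed=int(seeds[0]))
            raw, labels = generate_clips(spec)
            clips = np.stack([
                standardize(RawRecording(r, pp.target_rate), pp).samples for r in raw])
        return clips, labels

    clips, labels = load_data()
    class_names = sorted(set(labels))
    log("data", n_clips=len(labels), classes=class_names)

    # ---- split -----------------------------------------------------------
    split = stratified_split(labels, seed=int(seeds[1]))
    log("split", train=len(split.train), val=len(split.val), test=len(split.test))

    # ---- augmentation (training partition only) ---------------------------
    targets = one_hot(labels, class_names)
    train_clips, train_targets = clips[split.train], targets[split.train]
    if config.augment_level is not None:
        aug_rng = np.random.default_rng(int(seeds[2]))
        extra_x, extra_y = augment_waveforms(train_clips, train_targets,
                                             config.augment_level, aug_rng,
                                             config.preprocess.target_rate)
        train_clips = np.concatenate([train_clips, extra_x])
        train_targets = np.concatenate([train_targets, extra_y])
        log("augment", level=config.augment_level, added=int(extra_x.shape[0]))

    # ---- features ----------------------------------------------------------
    @_stage("features")
    def make_features():
        feat = config.features
        tb = bundle([extract_features_from_array(c, feat) for c in train_clips])
        vb = bundle([extract_features_from_array(c, feat) for c in clips[split.val]])
        eb = bundle([extract_features_from_array(c, feat) for c in clips[split.test]])
        return tb, vb, eb

    train_b, val_b, test_b = make_features()
    log("features", mfcc=list(train_b.x_mfcc.shape), mel=list(train_b.x_mel.shape))

    # ---- optional hyperparameter search ------------------------------------
    train_cfg = dataclasses.replace(config.train)
    if config.optimize_hyperparams:
        @_stage("optimize")
        def search():
            space = SearchSpace([
                Dimension("lr", 1e-4, 1e-2, scale="log"),
                Dimension("dropout", 0.0, 0.5),
            ])

            def fitness(params: dict) -> float:
                m = build_model(config.preset, len(class_names), seed=int(seeds[3]))
                m.dropout.p = params["dropout"]
                cfg_h = dataclasses.replace(train_cfg, lr=params["lr"], max_epochs=3,
                                            patience=3, seed=int(seeds[3]))
                train(m, train_b, train_targets, val_b, targets[split.val], cfg_h)
                acc = evaluate_accuracy(m, val_b, targets[split.val])
                return 1.0 - acc

            hs_cfg = dataclasses.replace(config.hs, seed=int(seeds[4]))
            return optimize(space, fitness, hs_cfg,
                            trace_path=os.path.join(run_dir, "hsobl_trace.jsonl"))

        result = search()
        train_cfg = dataclasses.replace(train_cfg, lr=result.best_params["lr"])
        log("optimize", best_params=result.best_params,
            best_fitness=result.best.fitness)

    # ---- final training -----------------------------------------------------
    @_stage("train")
    def fit():
        m = build_model(config.preset, len(class_names), seed=int(seeds[5]))
        hist = train(m, train_b, train_targets, val_b, targets[split.val],
                     dataclasses.replace(train_cfg, seed=int(seeds[5])),
                     max_steps=config.max_steps,
                     stop_at_val_accuracy=config.stop_at_val_accuracy)
        return m, hist

    model, history = fit()
    log("train", epochs=len(history.train_loss), steps=history.steps,
        stopped_early=history.stopped_early)

    # ---- evaluation ---------------------------------------------------------
    @_stage("evaluate")
    def score() -> MetricsReport:
        return evaluate(model, test_b, targets[split.test], class_names)

    report = score()
    with open(os.path.join(run_dir, "metrics.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    np.savetxt(os.path.join(run_dir, "confusion.csv"), report.confusion,
               fmt="%d", delimiter=",", header=",".join(report.labels))
    log("evaluate", accuracy=report.accuracy, macro_f1=report.macro_f1,
        mcc=report.mcc_macro)

    # ---- explanation --------------------------------------------------------
    @_stage("explain")
    def explain():
        idx = split.test[0]
        cls = class_names.index(labels[idx])
        cam = grad_cam(model,
                       test_b.x_mfcc[:1], test_b.x_wav[:1], test_b.x_mel[:1],
                       target_class=cls, stream="melspec")
        _save_heatmap(cam.heatmap, os.path.join(run_dir, "gradcam_melspec.png"))
        return cam

    cam = explain()
    log("explain", stream=cam.stream, target_class=cam.target_class)

    import lungsound
    log("provenance", numpy=np.__version__, package=lungsound.__version__,
        seed=config.seed)
    with open(os.path.join(run_dir, "events.jsonl"), "w") as fh:
        for e in events:
            fh.write(json.dumps(e) + "\n")
    return run_dir


def _save_heatmap(heatmap: np.ndarray, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.imshow(heatmap, aspect="auto", origin="lower", cmap="magma")
    ax.set_xlabel("frame")
    ax.set_ylabel("band")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
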