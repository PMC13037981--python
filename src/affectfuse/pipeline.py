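"""End-to-end run orchestration from a YAML config.

A run config composes the synthetic-corpus spec, split parameters, model /
loss / training settings, an output directory and one global seed.  The
global seed fans out to per-stage seeds through ``numpy.random.SeedSequence``
spawning, so each stage is independently reproducible.  The resolved config
is echoed into the run directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .data import build_feature_dataset
from .model import EmotionFusionModel
from .network import ModelConfig
from .preprocess import make_split
from .synthetic import SyntheticSpec, generate_corpus, write_archive, read_archive
from .train import LossConfig, TrainConfig

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

_ALLOWED_TOP = {"synthetic", "archive", "split", "model", "loss", "train",
                "label_dims", "out_dir", "seed"}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    h = np.random.SeedSequence(
        [int(global_seed)] + [ord(c) for c in stage]).generate_state(1)[0]
    return int(h % (2 ** 31))


class RunConfig:
    """Validated composition of all stage configs."""

    def __init__(self, raw: dict):
        unknown = set(raw) - _ALLOWED_TOP
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValueError("config must set out_dir")
        self.seed = int(raw.get("seed", 0))
        self.out_dir = Path(raw["out_dir"])
        self.archive = raw.get("archive")
        syn = raw.get("synthetic")
        if syn is None and self.archive is None:
            raise ValueError("config must provide either 'synthetic' or 'archive'")
        self.synthetic = None
        if syn is not None:
            syn = dict(syn)
            for key in ("eeg_channels", "peripheral_channels", "rating_dims"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            syn.setdefault("seed", stage_seed(self.seed, "synth"))
            self.synthetic = SyntheticSpec(**syn)
        self.label_dims = tuple(raw.get("label_dims", ("valence", "arousal")))
        split = dict(raw.get("split", {}))
        self.n_test_subjects = int(split.pop("n_test_subjects", 1))
        self.val_ratio = float(split.pop("val_ratio", 0.2))
        if split:
            raise ValueError(f"unknown split keys: {sorted(split)}")
        self.model = ModelConfig.from_dict(
            {**raw.get("model", {}), "label_dims": self.label_dims})
        self.loss = LossConfig(**raw.get("loss", {}))
        self.train = TrainConfig(**raw.get("train", {}))
        self.train.seed = stage_seed(self.seed, "train")
        self.raw = raw

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: str | Path | dict, verbose: bool = False) -> Path:
    """Synthesize (or load), featurize, split, train, evaluate; return run dir."""
    cfg = config if isinstance(config, RunConfig) else (
        RunConfig(config) if isinstance(config, dict) else RunConfig.from_yaml(config))
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    resolved = dict(cfg.raw)
    resolved["seed"] = cfg.seed
    (out / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=False))

    if cfg.synthetic is not None:
        trials = generate_corpus(cfg.synthetic)
        write_archive(trials, out / "corpus.h5")
    else:
        trials = read_archive(cfg.archive)

    ds = build_feature_dataset(trials, label_dims=cfg.label_dims)
    ds.save(out / "features.h5")
    subjects = sorted({t.subject_id for t in trials})
    per_subject = {s: sorted({t.trial_id for t in trials if t.subject_id == s})
                   for s in subjects}
    split = make_split(subjects, per_subject, cfg.n_test_subjects,
                       val_ratio=cfg.val_ratio, seed=stage_seed(cfg.seed, "split"))
    split.to_yaml(out / "split.yaml")

    model = EmotionFusionModel(ds, split, config=cfg.model,
                               loss_config=cfg.loss, train_config=cfg.train)
    results = model.fit(verbose=verbose)
    results.save(out)
    return out
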