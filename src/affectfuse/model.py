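"""Model/Results facade over the full pipeline.

``EmotionFusionModel`` is constructed from data (a featurized corpus and a
split plan, or raw trials via :meth:`from_trials`); ``fit`` trains the
configured network variant and returns an ``EmotionFusionResults`` carrying
the trained network, the per-epoch history, the held-out-subject evaluation
report, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import FeatureDataset, SequenceIndex, build_feature_dataset, scatter_matrix
from .evaluate import EvalReport, evaluate_model
from .features import default_gridmap, ElectrodeGridMap
from .network import CdomNet, ModelConfig, load_checkpoint, save_checkpoint
from .preprocess import SplitPlan, make_split
from .synthetic import TrialRecord
from .train import LossConfig, TrainConfig, TrainingHistory, fit as _fit

__all__ = ["EmotionFusionModel", "EmotionFusionResults"]


class EmotionFusionModel:
    """Multimodal emotion classifier over window sequences.

    Parameters
    ----------
    dataset : FeatureDataset
        Featurized corpus (DE values, peripheral statistics, pooled traces).
    split : SplitPlan
        Subject-independent trial-wise partition.
    config, loss_config, train_config : optional
        Architecture / loss / optimization settings; defaults are the fixed
        reference values.
    gridmap : optional ElectrodeGridMap
        Electrode placement; inferred from the channel roster by default.
    """

    def __init__(self, dataset: FeatureDataset, split: SplitPlan,
                 config: ModelConfig | None = None,
                 loss_config: LossConfig | None = None,
                 train_config: TrainConfig | None = None,
                 gridmap: ElectrodeGridMap | None = None):
        self.dataset = dataset
        self.split = split
        self.config = config or ModelConfig(
            label_dims=tuple(dataset.label_dims))
        if tuple(self.config.label_dims) != tuple(dataset.label_dims):
            self.config.label_dims = tuple(dataset.label_dims)
        self.loss_config = loss_config or LossConfig()
        self.train_config = train_config or TrainConfig()
        if gridmap is None:
            montage = "deap32" if len(dataset.eeg_channel_names) == 32 else "dreamer14"
            gridmap = default_gridmap(montage)
        self.gridmap = gridmap
        self._seqs = SequenceIndex.build(dataset, self.config.seq_len,
                                         self.config.seq_stride)

    @classmethod
    def from_trials(cls, trials: Sequence[TrialRecord], n_test_subjects: int,
                    seed: int = 0, label_dims: Sequence[str] = ("valence", "arousal"),
                    **kwargs) -> "EmotionFusionModel":
        """Featurize raw trials and derive the split in one step."""
        ds = build_feature_dataset(trials, label_dims=label_dims)
        subjects = sorted({t.subject_id for t in trials})
        per_subject = {s: sorted({t.trial_id for t in trials if t.subject_id == s})
                       for s in subjects}
        split = make_split(subjects, per_subject, n_test_subjects, seed=seed)
        return cls(ds, split, **kwargs)

    def _network(self, seed: int) -> CdomNet:
        S = scatter_matrix(self.gridmap, self.dataset.eeg_channel_names)
        return CdomNet(self.config, len(self.dataset.eeg_channel_names),
                       self.dataset.de.shape[-1],
                       len(self.dataset.peripheral_channel_names), S, seed=seed)

    def _fit_scaler(self, train_seqs: SequenceIndex) -> dict:
        """Per-feature standardization statistics from the training windows.

        Puts all network inputs on a unit scale, which conditions the
        optimization; the transform is stored with the checkpoint and
        applied identically at inference.
        """
        rows = np.unique(train_seqs.rows)
        scaler = {}
        for key, arr, axes in (("de", self.dataset.de[rows], (0,)),
                               ("per_stats", self.dataset.per_stats[rows], (0,)),
                               ("per_pooled", self.dataset.per_pooled[rows], (0, 2))):
            mu = arr.mean(axis=axes, keepdims=True)[0]
            sd = arr.std(axis=axes, keepdims=True)[0]
            scaler[key] = (mu, np.where(sd > 0, sd, 1.0))
        return scaler

    def fit(self, seed: int | None = None, verbose: bool = False) -> "EmotionFusionResults":
        """Train on the train partition, select on validation, score on test."""
        if seed is not None:
            self.train_config.seed = seed
        net = self._network(self.train_config.seed)
        train_seqs = self._seqs.select(self.dataset, self.split, "train")
        val_seqs = self._seqs.select(self.dataset, self.split, "val")
        net.input_scaler = self._fit_scaler(train_seqs)
        net, hist = _fit(net, self.dataset, train_seqs, val_seqs,
                         self.train_config, self.loss_config, verbose=verbose)
        try:
            test_seqs = self._seqs.select(self.dataset, self.split, "test")
            report = evaluate_model(net, self.dataset, test_seqs)
        except ValueError:
            report = None
        return EmotionFusionResults(model=self, network=net, history=hist,
                                    report=report)


@dataclass
class EmotionFusionResults:
    """Outcome of one training run: network, history, held-out evaluation."""

    model: EmotionFusionModel
    network: CdomNet
    history: TrainingHistory
    report: EvalReport | None

    @property
    def best_val_accuracy(self) -> float:
        return float(max(self.history.val_accuracy))

    @property
    def n_epochs(self) -> int:
        return len(self.history.epoch)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history.as_dict())

    def test_accuracy(self, dim: str | None = None) -> float:
        """Held-out-subject accuracy (percent), per dimension or averaged."""
        if self.report is None:
            raise ValueError("no test partition was evaluated")
        per = self.report.per_dimension
        if dim is not None:
            return per[dim]["accuracy"]
        return float(np.mean([m["accuracy"] for m in per.values()]))

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Emotion fusion model results",
            "=" * 60,
            f"variant:            {cfg.variant}",
            f"label dimensions:   {', '.join(cfg.label_dims)}",
            f"parameters:         {self.network.n_parameters():,}",
            f"epochs run:         {self.n_epochs}",
            f"best val accuracy:  {100 * self.best_val_accuracy:.2f}%",
        ]
        if self.report is not None:
            lines.append("-" * 60)
            lines.append(f"{'dimension':<12}{'acc%':>8}{'prec%':>8}{'sens%':>8}"
                         f"{'spec%':>8}{'F1%':>8}")
            for dim, m in self.report.per_dimension.items():
                def _f(v):
                    return f"{v:8.2f}" if v is not None else "      --"
                lines.append(f"{dim:<12}" + "".join(
                    _f(m[k]) for k in ("accuracy", "precision", "sensitivity",
                                       "specificity", "f1")))
            ps = self.report.per_subject
            acc_cols = [c for c in ps.columns if c.startswith("accuracy_")]
            if len(ps) and acc_cols:
                mean = ps[acc_cols].to_numpy().mean()
                sd = ps[acc_cols].to_numpy().mean(axis=1).std(ddof=1) if len(ps) > 1 else 0.0
                lines.append("-" * 60)
                lines.append(f"per-subject accuracy: {mean:.2f}% +/- {sd:.2f}% "
                             f"({len(ps)} test subjects)")
        return "\n".join(lines)

    def save(self, directory: str | Path) -> Path:
        """Checkpoint, history CSV, and evaluation JSON into a directory."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        save_checkpoint(self.network, d / "checkpoint.npz",
                        extra={"best_val_accuracy": self.best_val_accuracy})
        self.history_frame().to_csv(d / "history.csv", index=False)
        if self.report is not None:
            self.report.to_json(d / "eval_report.json")
            if self.report.channel_weights is not None:
                self.report.channel_weights.to_csv(d / "channel_weights.csv",
                                                   index=False)
        (d / "summary.txt").write_text(self.summary() + "\n")
        return d
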