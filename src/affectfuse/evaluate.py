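"""Metrics, per-subject reports, channel-weight summaries, ablation tables.

All rates are percentages.  A metric whose denominator is zero (e.g.
precision with no positive predictions) is reported as None ("undefined"),
never silently as 0.  The ablation harness trains each model variant over
several seeded runs, tabulates mean +/- SD accuracy per dimension, and runs
a one-way ANOVA across variants with Tukey's HSD post-hoc test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .data import FeatureDataset, SequenceIndex
from .network import CdomNet

__all__ = [
    "EvalReport",
    "ablation_compare",
    "channel_weight_summary",
    "confusion_metrics",
    "evaluate_model",
    "per_subject_report",
]


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Accuracy/precision/sensitivity/specificity/F1 (percent) + 2x2 counts."""
    y = np.asarray(y_true, dtype=int).ravel()
    p = np.asarray(y_pred, dtype=int).ravel()
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if not set(np.unique(np.concatenate([y, p]))) <= {0, 1}:
        raise ValueError("binary labels required")
    tp = int(((y == 1) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())

    def ratio(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    precision = ratio(tp, tp + fp)
    sensitivity = ratio(tp, tp + fn)
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "accuracy": ratio(tp + tn, len(y)),
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": ratio(tn, tn + fp),
        "f1": f1,
        "confusion": np.array([[tn, fp], [fn, tp]]),
    }


@dataclass
class EvalReport:
    """Evaluation of one model on one window/sequence set."""

    per_dimension: dict[str, dict]           # dim -> confusion_metrics output
    per_subject: pd.DataFrame                # subject x dimension accuracies
    channel_weights: pd.DataFrame | None     # per-channel attention summary
    n_samples: int

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "n_samples": self.n_samples,
            "per_dimension": {
                d: {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in m.items()}
                for d, m in self.per_dimension.items()},
            "per_subject": self.per_subject.to_dict(orient="list"),
        }
        if self.channel_weights is not None:
            payload["channel_weights"] = self.channel_weights.to_dict(orient="list")
        Path(path).write_text(json.dumps(payload, indent=2))
        return Path(path)


def _predict(model: CdomNet, ds: FeatureDataset, seqs: SequenceIndex,
             batch_size: int = 128) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    preds = {d: [] for d in ds.label_dims}
    labels, subjects = [], []
    for lo in range(0, len(seqs), batch_size):
        idx = np.arange(lo, min(lo + batch_size, len(seqs)))
        b = seqs.batch(ds, idx)
        probs = model.predict_proba(b["de"], b["per_pooled"], b["per_stats"])
        for dim in ds.label_dims:
            preds[dim].append(probs[dim].argmax(axis=1))
        labels.append(b["labels"])
        subjects.append(b["subject_ids"])
    return ({d: np.concatenate(v) for d, v in preds.items()},
            np.concatenate(labels), np.concatenate(subjects))


def per_subject_report(preds: Mapping[str, np.ndarray], labels: np.ndarray,
                       subjects: np.ndarray, label_dims: Sequence[str]) -> pd.DataFrame:
    """Accuracy per held-out subject per dimension (percent)."""
    rows = []
    for s in np.unique(subjects):
        m = subjects == s
        row = {"subject": int(s), "n": int(m.sum())}
        for d, dim in enumerate(label_dims):
            row[f"accuracy_{dim}"] = 100.0 * float(
                (preds[dim][m] == labels[m, d]).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def channel_weight_summary(model: CdomNet, ds: FeatureDataset,
                           seqs: SequenceIndex, batch_size: int = 128,
                           max_batches: int = 8) -> pd.DataFrame | None:
    """Mean attention weight per channel, with the above-grand-mean flag.

    Weights are averaged over windows; the grand mean over channels is the
    reference, and a channel counts as important when its mean weight is
    strictly above it.  Returns None for variants without channel attention.
    """
    if not model.config.use_channel_attention:
        return None
    from .autograd import no_grad
    eeg_w, per_w = [], []
    model.eval()
    with no_grad():
        for bi, lo in enumerate(range(0, len(seqs), batch_size)):
            if bi >= max_batches:
                break
            idx = np.arange(lo, min(lo + batch_size, len(seqs)))
            b = seqs.batch(ds, idx)
            out = model(b["de"], b["per_pooled"], b["per_stats"])
            eeg_w.append(out["eeg_channel_weights"].data)
            per_w.append(out["peripheral_channel_weights"].data)
    eeg_mean = np.concatenate(eeg_w).mean(axis=0)
    per_mean = np.concatenate(per_w).mean(axis=0)
    names = list(ds.eeg_channel_names) + list(ds.peripheral_channel_names)
    weights = np.concatenate([eeg_mean, per_mean])
    modality = ["eeg"] * len(eeg_mean) + ["peripheral"] * len(per_mean)
    df = pd.DataFrame({"channel": names, "modality": modality, "mean_weight": weights})
    for mod in ("eeg", "peripheral"):
        sel = df["modality"] == mod
        grand = df.loc[sel, "mean_weight"].mean()
        df.loc[sel, "above_average"] = df.loc[sel, "mean_weight"] > grand
    return df.sort_values("mean_weight", ascending=False).reset_index(drop=True)


def evaluate_model(model: CdomNet, ds: FeatureDataset,
                   seqs: SequenceIndex) -> EvalReport:
    """Pure function of predictions and labels (plus the weight summary)."""
    preds, labels, subjects = _predict(model, ds, seqs)
    per_dim = {dim: confusion_metrics(labels[:, d], preds[dim])
               for d, dim in enumerate(ds.label_dims)}
    subj = per_subject_report(preds, labels, subjects, ds.label_dims)
    cw = channel_weight_summary(model, ds, seqs)
    return EvalReport(per_dimension=per_dim, per_subject=subj,
                      channel_weights=cw, n_samples=labels.shape[0])


def ablation_compare(run_fn: Callable[[str, int], Mapping[str, float]],
                     variants: Sequence[str] = ("DO", "CDO", "DOM", "CDOM"),
                     n_runs: int = 3, seed: int = 0) -> dict:
    """Train every variant over seeded repeats and compare accuracies.

    ``run_fn(variant, run_seed)`` must return per-dimension accuracies
    (percent).  Returns a table of mean +/- SD per variant and dimension,
    plus one-way ANOVA and Tukey HSD p-values across variants (computed on
    the accuracies averaged over dimensions).  With fewer than 2 runs per
    variant the significance block is omitted with a warning flag.
    """
    seeds = [seed + 1000 * r for r in range(n_runs)]
    acc: dict[str, list[Mapping[str, float]]] = {v: [] for v in variants}
    for v in variants:
        for s in seeds:
            acc[v].append(run_fn(v, s))
    dims = sorted({d for runs in acc.values() for r in runs for d in r})
    rows = []
    for v in variants:
        for d in dims:
            vals = np.array([r[d] for r in acc[v]])
            rows.append({"variant": v, "dimension": d,
                         "mean_accuracy": float(vals.mean()),
                         "sd_accuracy": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                         "n_runs": len(vals)})
    table = pd.DataFrame(rows)
    result = {"table": table, "per_run": {
        v: [dict(r) for r in runs] for v, runs in acc.items()}}
    if n_runs < 2:
        result["warning"] = "significance omitted: need >= 2 runs per variant"
        return result
    groups = [np.array([np.mean(list(r.values())) for r in acc[v]]) for v in variants]
    if all(np.allclose(g, groups[0], atol=1e-12) and g.std() == 0 for g in groups):
        anova_p = 1.0  # identical accuracies everywhere: no variance to test
        posthoc = None
    else:
        anova = spstats.f_oneway(*groups)
        anova_p = float(anova.pvalue) if np.isfinite(anova.pvalue) else 1.0
        tk = spstats.tukey_hsd(*groups)
        posthoc = {f"{variants[i]} vs {variants[j]}": float(tk.pvalue[i, j])
                   for i in range(len(variants)) for j in range(i + 1, len(variants))}
    result["anova_p"] = anova_p
    result["posthoc_tukey_p"] = posthoc
    return result
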