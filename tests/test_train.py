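"""Loss functions, schedule, augmentation, optimizer, early stopping."""

import numpy as np
import pytest

import affectfuse.train as tr
from affectfuse import mi
from affectfuse.autograd import Tensor
from affectfuse.data import SequenceIndex, build_feature_dataset
from affectfuse.features import de_volume, default_gridmap
from affectfuse.preprocess import SignalWindow, make_split
from affectfuse.train import (
    LossConfig, TrainConfig, augment, augment_feature_batch, cross_entropy,
    fit, lr_at, mi_loss, softbin_mi_label, total_loss,
)
from conftest import small_model_config


# -- cross-entropy ---------------------------------------------------------

def test_cross_entropy_reference_values():
    y = np.array([1, 0, 1])
    assert cross_entropy(y, np.array([1.0, 0.0, 1.0])) == pytest.approx(0.0, abs=1e-10)
    assert cross_entropy(y, np.full(3, 0.5)) == pytest.approx(np.log(2), abs=1e-12)
    p = np.array([0.9, 0.2, 0.6])
    hand = -(np.log(0.9) + np.log(0.8) + np.log(0.6)) / 3
    assert cross_entropy(y, p) == pytest.approx(hand, abs=1e-12)
    with pytest.raises(ValueError):
        cross_entropy(y, np.array([0.5, 0.5]))


def test_total_loss_weighting():
    cfg = LossConfig()
    assert total_loss(1.0, 0.0, cfg) == pytest.approx(0.6)
    assert total_loss(0.0, 0.0, cfg) == 0.0
    assert total_loss(2.0, 3.0, cfg) == pytest.approx(0.6 * 2 + 0.2 * 3)
    with pytest.raises(ValueError):
        LossConfig(alpha=-0.1)


def test_lr_schedule():
    cfg = TrainConfig()
    assert lr_at(0, cfg) == pytest.approx(1e-4)
    assert lr_at(4, cfg) == pytest.approx(1e-4)
    assert lr_at(5, cfg) == pytest.approx(9e-5)
    assert lr_at(10, cfg) == pytest.approx(8.1e-5)
    with pytest.raises(ValueError):
        lr_at(-1, cfg)


# -- MI loss ---------------------------------------------------------------

def test_mi_loss_vanishes_under_independence(rng):
    n = 4000
    fused = rng.standard_normal(n)
    y = rng.integers(0, 2, n)
    a, b = rng.standard_normal(n), rng.standard_normal(n)
    assert abs(mi_loss(fused, [a, b], y)) < 0.05


def test_mi_loss_duplicated_modality_raises_penalty(rng):
    n = 2000
    fused = rng.standard_normal(n)
    y = rng.integers(0, 2, n)
    a, b = rng.standard_normal(n), rng.standard_normal(n)
    # duplication adds lambda * H(A) ~ 0.1 * ln(16) to the penalty term
    assert mi_loss(fused, [a, a], y) > mi_loss(fused, [a, b], y) + 0.2
    with pytest.raises(ValueError):
        mi_loss(fused, [a], y)


def test_mi_loss_exact_on_enumerated_distribution():
    """Features perfectly aligned with labels on a 2x2 joint; every term of
    the loss is computable by hand."""
    y = np.repeat([0, 1], 50)
    f = y.astype(float)  # I(F;Y) = H(Y) = ln 2
    a = f.copy()
    b = 1.0 - f  # I(A;B) = ln 2 as well
    cfg = LossConfig()
    expected = -np.log(2) + cfg.lam * np.log(2)
    assert mi_loss(f, [a, b], y, cfg) == pytest.approx(expected, abs=1e-10)


def test_softbin_mi_tracks_plugin_estimator(rng):
    n = 600
    y = rng.integers(0, 2, n)
    informative = y + 0.1 * rng.standard_normal(n)
    noise = rng.standard_normal(n)
    hi = float(softbin_mi_label(Tensor(informative[:, None]), y).data)
    lo = float(softbin_mi_label(Tensor(noise[:, None]), y).data)
    assert hi > 0.4 and abs(lo) < 0.1
    assert hi == pytest.approx(mi.feature_label_mi(informative, y), abs=0.2)


def test_softbin_mi_gradient_flows(rng):
    x = Tensor(rng.standard_normal((100, 2)), requires_grad=True)
    y = rng.integers(0, 2, 100)
    out = softbin_mi_label(x, y)
    out.backward()
    assert x.grad is not None and np.isfinite(x.grad).all()


# -- augmentation ----------------------------------------------------------

def _window(rng):
    return SignalWindow(1, 1, 0, 0, rng.standard_normal((2, 384)),
                        rng.standard_normal((3, 384)), {"valence": 1}, 128.0,
                        ("Fp1", "Fp2"), ("a", "b", "c"))


def test_augment_identity_and_bounds(rng):
    w = _window(rng)
    cfg = TrainConfig(time_shift_s=0.0, amp_scale=(1.0, 1.0))
    out = augment(w, cfg, rng)
    np.testing.assert_array_equal(out.eeg, w.eeg)
    np.testing.assert_array_equal(out.peripheral, w.peripheral)
    assert out.labels == w.labels
    cfg = TrainConfig()
    scales, shifts = [], []
    base_norm = np.linalg.norm(w.eeg)
    for _ in range(500):
        a = augment(w, cfg, rng)
        scales.append(np.linalg.norm(a.eeg) / base_norm)
    assert 0.9 <= min(scales) and max(scales) <= 1.1


def test_scaling_shifts_de_by_log_scale(rng):
    w = _window(rng)
    cfg = TrainConfig(time_shift_s=0.0, amp_scale=(1.25, 1.25))
    out = augment(w, cfg, rng)
    g = default_gridmap("deap32")
    before = de_volume(w.eeg, ["Fp1", "Fp2"], g, fs=128).values
    after = de_volume(out.eeg, ["Fp1", "Fp2"], g, fs=128).values
    mask = before != 0
    np.testing.assert_allclose(after[mask] - before[mask], np.log(1.25),
                               atol=1e-9)


def test_feature_level_augmentation_matches_closed_form(rng):
    batch = {
        "de": rng.standard_normal((4, 2, 32, 4)),
        "per_stats": np.abs(rng.standard_normal((4, 2, 8, 5))),
        "per_pooled": rng.standard_normal((4, 2, 8, 16)),
        "labels": np.ones((4, 2), dtype=int),
    }
    cfg = TrainConfig(time_shift_s=0.0, amp_scale=(1.25, 1.25))
    out = augment_feature_batch(batch, cfg, rng)
    np.testing.assert_allclose(out["de"] - batch["de"], np.log(1.25), atol=1e-12)
    np.testing.assert_allclose(out["per_stats"][..., :3],
                               1.25 * batch["per_stats"][..., :3])
    np.testing.assert_allclose(out["per_stats"][..., 3:],
                               batch["per_stats"][..., 3:])
    np.testing.assert_array_equal(out["labels"], batch["labels"])


# -- fit loop --------------------------------------------------------------

def _tiny_training_setup(tiny_corpus, tiny_dataset, variant="CDOM", seed=0):
    import affectfuse as af
    cfg = small_model_config(variant=variant)
    subjects = sorted({t.subject_id for t in tiny_corpus})
    per = {s: sorted({t.trial_id for t in tiny_corpus if t.subject_id == s})
           for s in subjects}
    split = make_split(subjects, per, 1, seed=3)
    model = af.EmotionFusionModel(tiny_dataset, split, config=cfg,
                                  train_config=TrainConfig(max_epochs=2, seed=seed))
    return model


def test_early_stopping_rule_trace(monkeypatch, tiny_corpus, tiny_dataset):
    """Validation curve .6 .7 .69 .68 .67: stop after 5 epochs, keep the
    weights of the second epoch."""
    curve = iter([0.6, 0.7, 0.69, 0.68, 0.67, 0.66, 0.65])
    snapshots = []

    def fake_accuracy(model, ds, seqs, batch_size=128):
        snapshots.append({n: p.data.copy() for n, p in model.named_parameters()})
        return next(curve)

    monkeypatch.setattr(tr, "_accuracy", fake_accuracy)
    model = _tiny_training_setup(tiny_corpus, tiny_dataset)
    model.train_config.max_epochs = 20
    res = model.fit()
    assert res.n_epochs == 5
    assert res.best_val_accuracy == pytest.approx(0.7)
    for name, p in res.network.named_parameters():
        np.testing.assert_array_equal(p.data, snapshots[1][name])


def test_fit_deterministic_under_seed(tiny_corpus, tiny_dataset):
    h1 = _tiny_training_setup(tiny_corpus, tiny_dataset, seed=5).fit().history
    h2 = _tiny_training_setup(tiny_corpus, tiny_dataset, seed=5).fit().history
    assert h1.train_loss == h2.train_loss
    assert h1.val_accuracy == h2.val_accuracy
    h3 = _tiny_training_setup(tiny_corpus, tiny_dataset, seed=6).fit().history
    assert h1.train_loss != h3.train_loss


def test_beta_zero_reduces_to_scaled_ce(tiny_corpus, tiny_dataset):
    model = _tiny_training_setup(tiny_corpus, tiny_dataset)
    model.loss_config = LossConfig(beta=0.0)
    model.train_config.max_epochs = 1
    res = model.fit()
    np.testing.assert_allclose(res.history.train_loss,
                               0.6 * np.array(res.history.train_ce), atol=1e-9)


def test_history_bounded_by_max_epochs(tiny_corpus, tiny_dataset):
    res = _tiny_training_setup(tiny_corpus, tiny_dataset).fit()
    assert res.n_epochs <= 2
    assert len(res.history.lr) == res.n_epochs
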