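"""Model facade, checkpoints, channel-weight summaries, pipeline, CLI."""

import numpy as np
import pytest
import yaml

import affectfuse as af
from affectfuse.data import SequenceIndex
from affectfuse.evaluate import channel_weight_summary
from affectfuse.network import load_checkpoint, save_checkpoint
from affectfuse.preprocess import make_split
from affectfuse.train import TrainConfig
from conftest import small_model_config


@pytest.fixture(scope="module")
def fitted(tiny_corpus, tiny_dataset):
    subjects = sorted({t.subject_id for t in tiny_corpus})
    per = {s: sorted({t.trial_id for t in tiny_corpus if t.subject_id == s})
           for s in subjects}
    split = make_split(subjects, per, 1, seed=3)
    model = af.EmotionFusionModel(tiny_dataset, split,
                                  config=small_model_config(),
                                  train_config=TrainConfig(max_epochs=2, seed=0))
    return model, model.fit()


def test_results_surface(fitted):
    model, res = fitted
    assert res.n_epochs <= 2
    assert 0.0 <= res.best_val_accuracy <= 1.0
    assert res.report is not None
    txt = res.summary()
    assert "variant" in txt and "valence" in txt and "arousal" in txt
    df = res.history_frame()
    assert list(df.columns[:2]) == ["epoch", "lr"]
    assert res.test_accuracy("valence") == \
        res.report.per_dimension["valence"]["accuracy"]


def test_checkpoint_round_trip_bit_exact(fitted, tmp_path, rng):
    _, res = fitted
    net = res.network
    save_checkpoint(net, tmp_path / "ck.npz")
    back = load_checkpoint(tmp_path / "ck.npz")
    de = rng.standard_normal((2, 3, 32, 4))
    pp = rng.standard_normal((2, 3, 8, 16))
    ps = rng.standard_normal((2, 3, 8, 5))
    a = net.predict_proba(de, pp, ps)
    b = back.predict_proba(de, pp, ps)
    for dim in a:
        np.testing.assert_array_equal(a[dim], b[dim])


def test_channel_weight_summary_structure(fitted, tiny_dataset):
    model, res = fitted
    seqs = model._seqs
    df = channel_weight_summary(res.network, tiny_dataset, seqs)
    assert set(df.columns) >= {"channel", "modality", "mean_weight", "above_average"}
    assert len(df) == 40  # 32 EEG + 8 peripheral
    for mod in ("eeg", "peripheral"):
        sub = df[df.modality == mod]
        grand = sub.mean_weight.mean()
        assert (sub.above_average == (sub.mean_weight > grand)).all()
    # descending by weight: the top row is the strongest channel
    assert df.mean_weight.is_monotonic_decreasing


def test_uniform_weights_give_empty_above_average_set(fitted, tiny_dataset):
    model, res = fitted
    net = res.network
    saved = {n: p.data.copy() for n, p in net.named_parameters()}
    try:
        for name, p in net.named_parameters():
            if name.startswith("ca_"):
                p.data = np.zeros_like(p.data)  # sigmoid(0) = 0.5 everywhere
        df = channel_weight_summary(net, tiny_dataset, model._seqs)
        np.testing.assert_allclose(df.mean_weight, 0.5)
        assert not df.above_average.any()  # strict inequality
    finally:
        for name, p in net.named_parameters():
            p.data = saved[name]


def test_do_variant_has_no_weight_summary(tiny_dataset, tiny_corpus):
    subjects = sorted({t.subject_id for t in tiny_corpus})
    per = {s: sorted({t.trial_id for t in tiny_corpus if t.subject_id == s})
           for s in subjects}
    split = make_split(subjects, per, 1, seed=3)
    model = af.EmotionFusionModel(tiny_dataset, split,
                                  config=small_model_config(variant="DO"))
    net = model._network(0)
    assert channel_weight_summary(net, tiny_dataset, model._seqs) is None


def test_feature_dataset_cache_round_trip(tiny_dataset, tmp_path):
    tiny_dataset.save(tmp_path / "features.h5")
    back = af.FeatureDataset.load(tmp_path / "features.h5")
    np.testing.assert_array_equal(back.de, tiny_dataset.de)
    np.testing.assert_array_equal(back.labels, tiny_dataset.labels)
    assert back.label_dims == tiny_dataset.label_dims
    assert back.eeg_channel_names == tiny_dataset.eeg_channel_names


def test_sequences_never_cross_trials(tiny_dataset):
    seqs = SequenceIndex.build(tiny_dataset, 6, 3)
    for i in range(len(seqs)):
        rows = seqs.rows[i]
        assert len(set(tiny_dataset.subject_ids[rows])) == 1
        assert len(set(tiny_dataset.trial_ids[rows])) == 1
        assert np.all(np.diff(tiny_dataset.window_index[rows]) == 1)


def _pipeline_config(tmp_path):
    return {
        "seed": 3,
        "out_dir": str(tmp_path / "run"),
        "synthetic": {"n_subjects": 2, "n_trials_per_subject": 4,
                      "stimulus_seconds": 12, "effect_size": 1.5},
        "split": {"n_test_subjects": 1},
        "model": {
            "dsc": {"channels": 8},
            "onlstm": {"hidden": 16, "chunk_factor": 4},
            "mha": {"heads": 2, "head_dim": 8, "hidden": 16},
            "spatial_embed_dim": 16, "peripheral_lstm_hidden": 4,
            "seq_len": 3, "seq_stride": 2,
        },
        "train": {"max_epochs": 1},
    }


def test_run_pipeline_products(tmp_path):
    out = af.run_pipeline(_pipeline_config(tmp_path), verbose=False)
    for name in ("config.yaml", "corpus.h5", "features.h5", "split.yaml",
                 "checkpoint.npz", "history.csv", "eval_report.json",
                 "summary.txt"):
        assert (out / name).exists(), name


def test_run_pipeline_rejects_bad_config(tmp_path):
    with pytest.raises(ValueError, match="unknown config keys"):
        af.run_pipeline({"out_dir": str(tmp_path), "bogus": 1, "synthetic": {}})
    with pytest.raises(ValueError, match="synthetic.*archive|archive"):
        af.run_pipeline({"out_dir": str(tmp_path)})


def test_cli_synth_featurize(tmp_path):
    from click.testing import CliRunner
    from affectfuse.cli import main
    runner = CliRunner()
    cfg = tmp_path / "spec.yaml"
    cfg.write_text(yaml.safe_dump({"n_subjects": 2, "n_trials_per_subject": 2,
                                   "stimulus_seconds": 8}))
    r = runner.invoke(main, ["synth", "--config", str(cfg), "--seed", "1",
                             "--out", str(tmp_path / "c.h5")])
    assert r.exit_code == 0, r.output
    r = runner.invoke(main, ["featurize", "--archive", str(tmp_path / "c.h5"),
                             "--out", str(tmp_path / "f.h5")])
    assert r.exit_code == 0, r.output
    ds = af.FeatureDataset.load(tmp_path / "f.h5")
    assert len(ds) > 0
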