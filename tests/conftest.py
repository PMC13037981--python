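import numpy as np
import pytest

import affectfuse as af
from affectfuse.network import DscConfig, MhaConfig, ModelConfig, OnLstmConfig


@pytest.fixture(scope="session")
def tiny_corpus():
    """3 subjects x 4 trials with short stimuli and a strong label effect."""
    spec = af.SyntheticSpec(n_subjects=3, n_trials_per_subject=4,
                            stimulus_seconds=20, seed=7, effect_size=1.5)
    return af.generate_corpus(spec)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_corpus):
    return af.build_feature_dataset(tiny_corpus)


@pytest.fixture(scope="session")
def gridmap():
    return af.default_gridmap("deap32")


def small_model_config(**overrides) -> ModelConfig:
    """A shrunken architecture for fast structural tests."""
    kw = dict(
        dsc=DscConfig(channels=8),
        onlstm=OnLstmConfig(hidden=16, chunk_factor=4),
        mha=MhaConfig(heads=2, head_dim=8, hidden=16),
        spatial_embed_dim=16,
        peripheral_lstm_hidden=4,
        seq_len=3,
        seq_stride=2,
    )
    kw.update(overrides)
    return ModelConfig(**kw)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
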