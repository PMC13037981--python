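"""Network blocks: attention oracles, ON-LSTM reduction, shapes, counts."""

import numpy as np
import pytest

from affectfuse.autograd import Tensor, no_grad
from affectfuse.data import scatter_matrix
from affectfuse.features import default_gridmap
from affectfuse.network import (
    CdomNet, ChannelAttention, DepthwiseConv2d, MhaConfig, ModelConfig,
    MultiHeadAttention, OnLstm, OnLstmCell, OnLstmConfig, PlainLstm,
    single_head_attention,
)
from conftest import small_model_config


# -- single-head attention -------------------------------------------------

def test_single_head_matches_loop_oracle(rng):
    Q = Tensor(rng.standard_normal((2, 1, 4)))
    K = Tensor(rng.standard_normal((2, 3, 4)))
    V = Tensor(rng.standard_normal((2, 3, 4)))
    ctx, scores = single_head_attention(Q, K, V)
    for b in range(2):
        raw = np.array([Q.data[b, 0] @ K.data[b, t] / np.sqrt(4) for t in range(3)])
        w = np.exp(raw - raw.max())
        w /= w.sum()
        expected = sum(w[t] * V.data[b, t] for t in range(3))
        np.testing.assert_allclose(ctx.data[b, 0], expected, atol=1e-6)
        np.testing.assert_allclose(scores.data[b, 0], w, atol=1e-6)
    np.testing.assert_allclose(scores.data.sum(axis=-1), 1.0, atol=1e-9)


def test_single_head_degenerate_cases(rng):
    Q = Tensor(rng.standard_normal((1, 1, 4)))
    V = Tensor(rng.standard_normal((1, 1, 4)))
    ctx, scores = single_head_attention(Q, Tensor(rng.standard_normal((1, 1, 4))), V)
    np.testing.assert_allclose(scores.data, 1.0)
    np.testing.assert_allclose(ctx.data, V.data)
    # identical keys -> uniform scores -> context is the mean of values
    K = Tensor(np.tile(rng.standard_normal((1, 1, 4)), (1, 5, 1)))
    V5 = Tensor(rng.standard_normal((1, 5, 4)))
    ctx, _ = single_head_attention(Q, K, V5)
    np.testing.assert_allclose(ctx.data[0, 0], V5.data[0].mean(axis=0), atol=1e-12)
    with pytest.raises(ValueError, match="head dims"):
        single_head_attention(Q, Tensor(np.zeros((1, 5, 3))), V5)


# -- multi-head attention --------------------------------------------------

def test_mha_output_dim_and_key_permutation_invariance(rng):
    cfg = MhaConfig()  # 8 heads x 64 = 512
    mha = MultiHeadAttention(cfg, np.random.default_rng(0))
    mha.eval()
    oall = Tensor(rng.standard_normal((2, 6, 512)))
    olast = Tensor(rng.standard_normal((2, 1, 512)))
    out = mha(oall, olast, np.random.default_rng(0))
    assert out.shape == (2, 512)
    perm = rng.permutation(6)
    out_p = mha(Tensor(oall.data[:, perm]), olast, np.random.default_rng(0))
    np.testing.assert_allclose(out.data, out_p.data, atol=1e-9)


def test_mha_config_validation():
    with pytest.raises(ValueError, match="head_dim"):
        MhaConfig(heads=8, head_dim=60, hidden=512)


# -- ON-LSTM ---------------------------------------------------------------

def _np_lstm_reference(x, W, U, b, hidden):
    """Plain LSTM forward in straight numpy (the reduction oracle)."""
    def sig(z):
        return 1 / (1 + np.exp(-z))
    B, T, _ = x.shape
    h = np.zeros((B, hidden))
    c = np.zeros((B, hidden))
    outs = []
    for t in range(T):
        pre = x[:, t] @ W + h @ U + b
        i = sig(pre[:, :hidden])
        f = sig(pre[:, hidden:2 * hidden])
        o = sig(pre[:, 2 * hidden:3 * hidden])
        g = np.tanh(pre[:, 3 * hidden:4 * hidden])
        c = f * c + i * g
        h = o * np.tanh(c)
        outs.append(h)
    return np.stack(outs, axis=1)


def test_onlstm_with_open_masters_reduces_to_standard_lstm(rng):
    cell = OnLstmCell(5, 8, 4, 1.0, np.random.default_rng(3), master_open=True)
    x = rng.standard_normal((2, 7, 5))
    h = Tensor(np.zeros((2, 8)))
    c = Tensor(np.zeros((2, 8)))
    outs = []
    with no_grad():
        for t in range(7):
            h, c = cell(Tensor(x[:, t]), h, c)
            outs.append(h.data)
    ref = _np_lstm_reference(x, cell.W.data, cell.U.data, cell.b.data, 8)
    np.testing.assert_allclose(np.stack(outs, axis=1), ref, atol=1e-5)


def test_onlstm_forget_bias_initialized_to_one():
    cell = OnLstmCell(3, 8, 4, 1.0, np.random.default_rng(0))
    np.testing.assert_allclose(cell.b.data[8:16], 1.0)
    np.testing.assert_allclose(np.delete(cell.b.data, np.s_[8:16]), 0.0)


def test_onlstm_sequence_outputs(rng):
    lstm = OnLstm(4, OnLstmConfig(hidden=8, layers=2, chunk_factor=4),
                  np.random.default_rng(1))
    lstm.eval()
    x1 = Tensor(rng.standard_normal((3, 1, 4)))
    oall, olast = lstm(x1, np.random.default_rng(0))
    np.testing.assert_allclose(oall.data, olast.data)  # T=1: all == last
    x6 = Tensor(rng.standard_normal((3, 6, 4)))
    oall, olast = lstm(x6, np.random.default_rng(0))
    assert oall.shape == (3, 6, 16) and olast.shape == (3, 1, 16)
    np.testing.assert_allclose(oall.data[:, -1:], olast.data)
    with pytest.raises(ValueError, match="T=0"):
        lstm(Tensor(np.zeros((2, 0, 4))), np.random.default_rng(0))


def test_onlstm_chunking_validation():
    with pytest.raises(ValueError, match="divisible"):
        OnLstmCell(3, 10, 4, 1.0, np.random.default_rng(0))


# -- depthwise separable CNN ----------------------------------------------

def test_depthwise_parameter_economy():
    """A depthwise 3x3 layer over 64 channels has 64*9 weights (+64 bias),
    against 64*64*9 for a full convolution — the point of the factorization."""
    layer = DepthwiseConv2d(64, 3, np.random.default_rng(0))
    n = sum(p.data.size for _, p in layer.named_parameters())
    assert n == 64 * 9 + 64
    assert n < 64 * 64 * 9


def test_cnn_zero_input_zero_prebias_output(rng):
    from affectfuse.network import DepthwiseSeparableCnn, DscConfig
    cnn = DepthwiseSeparableCnn(4, DscConfig(channels=8), np.random.default_rng(0))
    cnn.eval()
    out = cnn(Tensor(np.zeros((2, 4, 9, 9))), rng)
    np.testing.assert_allclose(out.data, 0.0)  # biases start at zero


# -- full model ------------------------------------------------------------

def _small_net(variant="CDOM", seed=0):
    cfg = small_model_config(variant=variant)
    S = scatter_matrix(default_gridmap("deap32"),
                       tuple(default_gridmap("deap32").mapping))
    return CdomNet(cfg, 32, 4, 8, S, seed=seed), cfg


def _batch(rng, B=3, T=3):
    return (rng.standard_normal((B, T, 32, 4)),
            rng.standard_normal((B, T, 8, 16)),
            rng.standard_normal((B, T, 8, 5)))


@pytest.mark.parametrize("variant", ["DO", "CDO", "DOM", "CDOM"])
def test_probabilities_sum_to_one_all_variants(variant, rng):
    net, _ = _small_net(variant)
    probs = net.predict_proba(*_batch(rng))
    for dim in ("valence", "arousal"):
        np.testing.assert_allclose(probs[dim].sum(axis=1), 1.0, atol=1e-9)


def test_eval_forward_deterministic_and_batch_order_invariant(rng):
    net, _ = _small_net()
    de, pp, ps = _batch(rng, B=4)
    p1 = net.predict_proba(de, pp, ps)
    p2 = net.predict_proba(de, pp, ps)
    np.testing.assert_array_equal(p1["valence"], p2["valence"])
    perm = np.array([2, 0, 3, 1])
    p3 = net.predict_proba(de[perm], pp[perm], ps[perm])
    np.testing.assert_allclose(p3["valence"], p1["valence"][perm], atol=1e-10)


def test_channel_attention_weights_in_unit_interval(rng):
    net, _ = _small_net("CDOM")
    net.eval()
    with no_grad():
        out = net(*_batch(rng))
    for key in ("eeg_channel_weights", "peripheral_channel_weights"):
        w = out[key].data
        assert np.all(w > 0) and np.all(w < 1)
    np.testing.assert_allclose(out["modality_weights"].data.sum(axis=1), 1.0,
                               atol=1e-12)


def test_cdom_with_neutral_attention_reduces_to_do(rng):
    """Forcing channel weights to 1 and making the attention head a
    pass-through of the last recurrent state turns CDOM into DO exactly."""
    do, _ = _small_net("DO", seed=5)
    cdom, _ = _small_net("CDOM", seed=9)
    # share every common submodule
    for attr in ("cnn", "embed", "per_lstm", "mod_score_eeg", "mod_score_per",
                 "temporal"):
        setattr(cdom, attr, getattr(do, attr))
    cdom.heads = do.heads
    cdom._head_list = do._head_list
    cdom.ca_eeg = lambda x: Tensor(np.ones(x.shape[:2]))
    cdom.ca_per = lambda x: Tensor(np.ones(x.shape[:2]))

    class _PassThrough:
        def modules(self):
            return iter(())

    cdom.proj = lambda x: x
    cdom.mha = lambda oall, olast, rng: olast.reshape(olast.shape[0], -1)
    batch = _batch(rng)
    do.eval()
    cdom.training = False
    with no_grad():
        np.testing.assert_allclose(cdom(*batch)["probs"]["valence"].data,
                                   do(*batch)["probs"]["valence"].data,
                                   atol=1e-12)


def test_parameter_count_matches_closed_form():
    net, cfg = _small_net("CDOM")
    C, nb, l = 32, 4, 8
    ch = cfg.dsc.channels
    cnn = (nb * 9 + nb) + (nb * ch + ch) + (ch * 9 + ch) + (ch * ch + ch)
    embed = ch * 81 * cfg.spatial_embed_dim + cfg.spatial_embed_dim
    hp = cfg.peripheral_lstm_hidden
    per_lstm = (1 + hp) * (4 * hp + 2) + (4 * hp + 2)  # chunk = hidden -> 2 masters
    d_per = l * (hp + 5)
    mod = (cfg.spatial_embed_dim + 1) + (d_per + 1)
    h, M = cfg.onlstm.hidden, cfg.onlstm.hidden // cfg.onlstm.chunk_factor
    gates = 4 * h + 2 * M
    d_in = cfg.spatial_embed_dim + d_per
    lstm1 = 2 * ((d_in + h + 1) * gates)
    lstm2 = 2 * ((2 * h + h + 1) * gates)
    Z, N, dh = cfg.mha.hidden, cfg.mha.heads, cfg.mha.head_dim
    proj = 2 * h * Z + Z
    mha = 3 * N * (Z * dh + dh) + 2 * Z
    r_eeg = 4  # reduction actually used for 32 channels
    ca_eeg = 2 * (C * (C // r_eeg)) + 2 * (C // r_eeg)
    ca_per = 2 * (l * (l // 4)) + 2 * (l // 4)
    heads = 2 * (Z * 2 + 2)
    expected = cnn + embed + per_lstm + mod + lstm1 + lstm2 + proj + mha + \
        ca_eeg + ca_per + heads
    assert net.n_parameters() == expected


def test_bad_input_shapes_rejected(rng):
    net, _ = _small_net()
    with pytest.raises(ValueError, match="inconsistent"):
        net(rng.standard_normal((2, 3, 30, 4)),
            rng.standard_normal((2, 3, 8, 16)),
            rng.standard_normal((2, 3, 8, 5)))


def test_variant_validation():
    with pytest.raises(ValueError, match="variant"):
        ModelConfig(variant="XYZ")
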