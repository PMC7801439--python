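"""Transformer core: attention vs loop oracle, PE closed form, causality,
learning-rate schedule, smoke training and checkpoint resume."""

import numpy as np
import pytest

from prot2drug.model import (
    AttentionParams,
    CheckpointMismatchError,
    ModelConfig,
    TrainConfig,
    Transformer,
    load_checkpoint,
    multihead_attention,
    noam_learning_rate,
    positional_encoding,
    save_checkpoint,
    scaled_dot_product_attention,
    train_model,
)
from prot2drug.tokenizer import build_vocabulary, encode, pad_batch

from oracles import attention_rowloop, multihead_rowloop


# --------------------------- attention ------------------------------- #


def test_single_query_single_key_returns_value():
    out = scaled_dot_product_attention(np.array([[2.0]]), np.array([[3.0]]), np.array([[7.0]]))
    np.testing.assert_allclose(out, [[7.0]])


def test_identical_keys_average_values():
    q = np.array([[1.0, 0.0]])
    k = np.array([[0.5, 0.5], [0.5, 0.5]])
    v = np.array([[1.0], [3.0]])
    np.testing.assert_allclose(scaled_dot_product_attention(q, k, v), [[2.0]], atol=1e-12)


def test_attention_matches_rowloop_oracle_on_random_instances(rng):
    """100 random instances agree with the per-row softmax loop to 1e-6."""
    for _ in range(100):
        m, n, dk, dv = rng.integers(1, 6, size=4)
        q = rng.standard_normal((m, dk))
        k = rng.standard_normal((n, dk))
        v = rng.standard_normal((n, dv))
        mask = rng.random((m, n)) < 0.8
        mask[:, 0] = True  # keep every row feasible
        np.testing.assert_allclose(
            scaled_dot_product_attention(q, k, v, mask),
            attention_rowloop(q, k, v, mask),
            atol=1e-6,
        )


def test_attention_rows_are_convex_combinations(rng):
    q = rng.standard_normal((4, 3))
    k = rng.standard_normal((5, 3))
    v = rng.standard_normal((5, 2))
    out = scaled_dot_product_attention(q, k, v)
    for col in range(v.shape[1]):
        assert out[:, col].min() >= v[:, col].min() - 1e-12
        assert out[:, col].max() <= v[:, col].max() + 1e-12


def test_fully_masked_row_rejected(rng):
    q = rng.standard_normal((2, 3))
    k = rng.standard_normal((4, 3))
    v = rng.standard_normal((4, 3))
    mask = np.ones((2, 4), bool)
    mask[1] = False
    with pytest.raises(ValueError, match="masked"):
        scaled_dot_product_attention(q, k, v, mask)


def test_attention_shape_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        scaled_dot_product_attention(
            rng.standard_normal((2, 3)), rng.standard_normal((4, 2)), rng.standard_normal((4, 3))
        )


def test_multihead_single_head_identity_projections_reduce_to_attention(rng):
    d = 4
    q = rng.standard_normal((3, d))
    k = rng.standard_normal((5, d))
    v = rng.standard_normal((5, d))
    eye = np.eye(d)
    params = AttentionParams(W_Q=[eye], W_K=[eye], W_V=[eye], W_O=eye)
    np.testing.assert_array_equal(
        multihead_attention(q, k, v, params), scaled_dot_product_attention(q, k, v)
    )


def test_multihead_matches_per_head_oracle(rng):
    d, dk, h = 6, 3, 2
    q = rng.standard_normal((4, d))
    k = rng.standard_normal((5, d))
    v = rng.standard_normal((5, d))
    W_Q = [rng.standard_normal((d, dk)) for _ in range(h)]
    W_K = [rng.standard_normal((d, dk)) for _ in range(h)]
    W_V = [rng.standard_normal((d, dk)) for _ in range(h)]
    W_O = rng.standard_normal((h * dk, d))
    np.testing.assert_allclose(
        multihead_attention(q, k, v, AttentionParams(W_Q, W_K, W_V, W_O)),
        multihead_rowloop(q, k, v, W_Q, W_K, W_V, W_O),
        atol=1e-8,
    )


def test_multihead_zero_output_projection(rng):
    d = 4
    q = rng.standard_normal((3, d))
    params = AttentionParams(
        W_Q=[np.eye(d)], W_K=[np.eye(d)], W_V=[np.eye(d)], W_O=np.zeros((d, d))
    )
    assert np.all(multihead_attention(q, q, q, params) == 0)


# ----------------------- positional encoding ------------------------- #


def test_pe_position_zero_is_zero_one_pattern():
    pe = positional_encoding(10, 8).PE
    np.testing.assert_array_equal(pe[0, 0::2], 0.0)
    np.testing.assert_array_equal(pe[0, 1::2], 1.0)


def test_pe_entries_bounded_and_spot_value():
    pe = positional_encoding(16, 12, pe_base=10000.0).PE
    assert np.all(pe >= -1.0) and np.all(pe <= 1.0)
    assert pe[3, 0] == pytest.approx(np.sin(3.0), abs=1e-6)  # ~0.14112
    assert pe[3, 1] == pytest.approx(np.cos(3.0), abs=1e-6)
    i = 2  # dimension pair index -> columns 4, 5
    arg = 3.0 / 10000.0 ** (2 * i / 12)
    assert pe[3, 4] == pytest.approx(np.sin(arg), abs=1e-6)
    assert pe[3, 5] == pytest.approx(np.cos(arg), abs=1e-6)


def test_pe_base_is_configurable():
    pe = positional_encoding(8, 4, pe_base=1000.0).PE
    assert pe[5, 2] == pytest.approx(np.sin(5.0 / 1000.0 ** (2 / 4)), abs=1e-6)


def test_pe_odd_dimension_rejected():
    with pytest.raises(ValueError):
        positional_encoding(4, 7)


# ------------------------- config / schedule -------------------------- #


def test_config_validates_divisibility():
    with pytest.raises(ValueError):
        ModelConfig(d_model=130, n_heads=4)


def test_noam_schedule_closed_form():
    d, w = 128, 4000
    for step in (1, w, 10 * w):
        expected = d**-0.5 * min(step**-0.5, step * w**-1.5)
        assert noam_learning_rate(step, d, w) == pytest.approx(expected, rel=1e-12)
    # warmup peak: both branches agree at step == warmup
    assert noam_learning_rate(w, d, w) == pytest.approx(d**-0.5 * w**-0.5, rel=1e-12)


# --------------------------- forward pass ----------------------------- #


@pytest.fixture(scope="module")
def tiny_model():
    cfg = ModelConfig(n_layers=2, d_model=16, n_heads=2, dropout=0.0,
                      max_source_len=50, max_target_len=30)
    return Transformer(cfg, vocab_size=12, seed=7)


def _toy_batch(rng, n, ls, lt, vocab_size=12):
    src = rng.integers(3, vocab_size, size=(n, ls))
    tgt = rng.integers(3, vocab_size, size=(n, lt))
    tgt[:, 0] = 1
    tgt[:, -1] = 2
    return src, np.ones_like(src, bool), tgt, np.ones_like(tgt, bool)


def test_decoder_rows_are_probability_vectors(tiny_model, rng):
    src, sm, tgt, tm = _toy_batch(rng, 3, 9, 6)
    memory = tiny_model.encode_memory(src, sm)
    probs = tiny_model.decoder_forward(tgt, memory, sm)
    assert probs.shape == (3, 6, 12)
    assert np.all(probs >= 0)
    np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)


def test_decoder_causality_under_future_perturbation(tiny_model, rng):
    """Changing token t+1 never changes the distribution at position t."""
    for _ in range(20):
        src, sm, tgt, tm = _toy_batch(rng, 1, 8, 7)
        memory = tiny_model.encode_memory(src, sm)
        base = tiny_model.decoder_forward(tgt, memory, sm)
        t = int(rng.integers(0, tgt.shape[1] - 1))
        perturbed = tgt.copy()
        perturbed[0, t + 1] = 3 + (perturbed[0, t + 1] - 3 + 1) % 9
        after = tiny_model.decoder_forward(perturbed, memory, sm)
        np.testing.assert_allclose(base[0, : t + 1], after[0, : t + 1], atol=1e-6)


def test_appending_token_preserves_earlier_rows(tiny_model, rng):
    src, sm, tgt, tm = _toy_batch(rng, 1, 8, 6)
    memory = tiny_model.encode_memory(src, sm)
    short = tiny_model.decoder_forward(tgt[:, :4], memory, sm)
    full = tiny_model.decoder_forward(tgt, memory, sm)
    np.testing.assert_allclose(short, full[:, :4], atol=1e-6)


def test_encoder_padding_independence(tiny_model, rng):
    """The same protein padded differently yields identical context rows."""
    src = rng.integers(3, 12, size=(1, 6))
    ids_a = np.concatenate([src, np.zeros((1, 4), np.int64)], axis=1)
    mask_a = np.concatenate([np.ones((1, 6), bool), np.zeros((1, 4), bool)], axis=1)
    ctx_padded = tiny_model.encoder_forward(ids_a, mask_a)[0]
    ctx_plain = tiny_model.encoder_forward(src, np.ones((1, 6), bool))[0]
    np.testing.assert_allclose(ctx_padded.z, ctx_plain.z, atol=1e-5)
    assert ctx_padded.z.shape == (6, tiny_model.config.d_model)


def test_inference_is_deterministic(tiny_model, rng):
    src, sm, tgt, tm = _toy_batch(rng, 2, 7, 5)
    memory1 = tiny_model.encode_memory(src, sm)
    memory2 = tiny_model.encode_memory(src, sm)
    np.testing.assert_array_equal(memory1, memory2)


def test_overlong_source_rejected(tiny_model):
    ids = np.zeros((1, 51), np.int64)
    with pytest.raises(ValueError, match="source length"):
        tiny_model.encode_memory(ids, np.ones_like(ids, bool))


# ----------------------------- training ------------------------------- #


@pytest.fixture(scope="module")
def smoke_run():
    pairs = [("MKWA", "CCO"), ("AWKM", "CCN"), ("KKWW", "COC"), ("WAMK", "CCC")] * 8
    vocab = build_vocabulary([x for p in pairs for x in p])
    cfg = ModelConfig(n_layers=2, d_model=32, n_heads=2, dropout=0.1,
                      max_source_len=10, max_target_len=10)
    tc = TrainConfig(steps=50, warmup_steps=20, batch_tokens=256, log_every=10)
    model, state = train_model(pairs, vocab, cfg, tc, seed=21)
    return pairs, vocab, cfg, tc, model, state


def test_training_loss_decreases(smoke_run):
    _, _, _, _, _, state = smoke_run
    first = state.log[0][2]
    last = state.log[-1][2]
    assert state.step == 50
    assert last < first


def test_training_deterministic_under_seed(smoke_run):
    pairs, vocab, cfg, tc, model, state = smoke_run
    model2, state2 = train_model(pairs, vocab, cfg, tc, seed=21)
    assert state2.loss == state.loss
    for k, v in model.params.items():
        np.testing.assert_array_equal(v.data, model2.params[k].data)


def test_checkpoint_roundtrip_and_resume_trajectory(smoke_run, tmp_path):
    """Stopping at step 30 and resuming reproduces the uninterrupted run."""
    pairs, vocab, cfg, tc, model, state = smoke_run
    tc30 = TrainConfig(steps=30, warmup_steps=20, batch_tokens=256, log_every=10)
    m30, s30 = train_model(pairs, vocab, cfg, tc30, seed=21)
    ckpt = tmp_path / "step30.ckpt"
    save_checkpoint(ckpt, m30, vocab, s30)

    resumed, rstate = train_model(pairs, vocab, cfg, tc, seed=21, resume_from=ckpt)
    assert rstate.loss == pytest.approx(state.loss, abs=1e-12)
    for k, v in model.params.items():
        np.testing.assert_array_equal(v.data, resumed.params[k].data)

    reloaded, rvocab, meta = load_checkpoint(ckpt)
    assert meta["step"] == 30
    assert rvocab.token_to_id == vocab.token_to_id
    np.testing.assert_array_equal(reloaded.params["src_embed"].data, m30.params["src_embed"].data)


def test_resume_refuses_vocabulary_mismatch(smoke_run, tmp_path):
    pairs, vocab, cfg, tc, model, state = smoke_run
    ckpt = tmp_path / "model.ckpt"
    save_checkpoint(ckpt, model, vocab, state)
    other_vocab = build_vocabulary(["ZZZZ", "QQQQ"])
    with pytest.raises(CheckpointMismatchError):
        train_model([("ZQ", "QZ")], other_vocab, cfg, tc, seed=0, resume_from=ckpt)
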