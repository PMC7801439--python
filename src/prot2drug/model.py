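"""Encoder-decoder transformer translating protein sequences into SMILES.

The encoder maps an amino-acid sequence (a_1..a_n) to continuous
representations z = (z_1..z_n); the decoder generates a SMILES string
autoregressively while attending to z.  Attention is scaled dot-product,

    Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V,

multihead attention projects Q, K, V ``h`` times with learned matrices,
computes the heads in parallel and projects their concatenation once more,
and token order enters through fixed sinusoidal positional encodings

    PE(pos, 2i)   = sin(pos / base^(2i / d_model))
    PE(pos, 2i+1) = cos(pos / base^(2i / d_model)).

Each encoder layer is multihead self-attention followed by a position-wise
feed-forward network; decoder layers add a source-attending multihead
sublayer in between.  Every sublayer is wrapped in a residual connection
and layer normalization (post-norm).  Training uses teacher forcing with
label-smoothed cross-entropy, the Adam optimizer, and the inverse-square-
root warmup learning-rate schedule

    lr(step) = d_model^(-1/2) * min(step^(-1/2), step * warmup^(-3/2)).

Everything runs on NumPy via the package's reverse-mode autodiff engine;
training is fully reproducible under a fixed seed on one device.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .tokenizer import (
    MAX_SOURCE_LEN,
    MAX_TARGET_LEN,
    TokenSequence,
    Vocabulary,
    encode,
    pad_batch,
)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainState",
    "AttentionParams",
    "ContextMatrix",
    "PositionalEncodingTable",
    "TrainingDivergedError",
    "CheckpointMismatchError",
    "positional_encoding",
    "scaled_dot_product_attention",
    "multihead_attention",
    "noam_learning_rate",
    "Transformer",
    "train_model",
    "save_checkpoint",
    "load_checkpoint",
]

_MASK_BIAS = -1e9


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class CheckpointMismatchError(RuntimeError):
    """Raised when a checkpoint's vocabulary does not match the data."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults: 4 layers, width 128, 4 heads)."""

    n_layers: int = 4
    d_model: int = 128
    n_heads: int = 4
    d_ff: int | None = None  # defaults to 4 * d_model
    dropout: float = 0.1
    pe_base: float = 10000.0
    label_smoothing: float = 0.1
    max_source_len: int = MAX_SOURCE_LEN
    max_target_len: int = MAX_TARGET_LEN

    def __post_init__(self):
        if self.d_ff is None:
            self.d_ff = 4 * self.d_model
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if min(self.n_layers, self.d_model, self.n_heads, self.d_ff) < 0 or self.d_model == 0:
            raise ValueError("dimensions must be positive")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    d_v = d_k


@dataclass
class TrainConfig:
    """Optimization hyperparameters for the desk-scale training runs."""

    steps: int = 2000
    warmup_steps: int = 400
    batch_tokens: int = 4096
    lr_scale: float = 1.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.98
    adam_eps: float = 1e-9
    weight_decay: float = 0.0  # decoupled (AdamW-style), off by default
    grad_clip: float = 1.0
    log_every: int = 50
    average_last: int = 0  # >0: average the last k weight snapshots
    snapshot_every: int = 250
    plain_ce_after: int | None = None  # step after which label smoothing is 0


@dataclass
class TrainState:
    """Progress of one training run; ``log`` rows are (step, lr, loss)."""

    step: int = 0
    learning_rate: float = 0.0
    loss: float = float("nan")
    seed: int = 0
    log: list = field(default_factory=list)


@dataclass
class PositionalEncodingTable:
    """Sinusoidal position signals, shape (max_len, d_model), entries in [-1, 1]."""

    PE: np.ndarray
    pe_base: float


def positional_encoding(
    max_len: int, d_model: int, pe_base: float = 10000.0
) -> PositionalEncodingTable:
    """Build the sinusoidal table; ``d_model`` must be even."""
    if d_model % 2 != 0:
        raise ValueError("d_model must be even for sin/cos positional encoding")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    pos = np.arange(max_len, dtype=np.float64)[:, None]
    i2 = np.arange(0, d_model, 2, dtype=np.float64)[None, :]
    angle = pos / np.power(pe_base, i2 / d_model)
    pe = np.empty((max_len, d_model), dtype=np.float64)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return PositionalEncodingTable(pe.astype(np.float32), float(pe_base))


def scaled_dot_product_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V for single matrices.

    ``Q`` is (m, d_k), ``K`` is (n, d_k), ``V`` is (n, d_v); ``mask`` is a
    boolean (m, n) array, True where attention is allowed.  Rows with no
    allowed position are rejected.
    """
    Q, K, V = (np.asarray(x, dtype=np.float64) for x in (Q, K, V))
    if Q.ndim != 2 or K.ndim != 2 or V.ndim != 2:
        raise ValueError("Q, K, V must be 2-D matrices")
    if Q.shape[1] != K.shape[1] or K.shape[0] != V.shape[0]:
        raise ValueError(
            f"incompatible shapes Q{Q.shape}, K{K.shape}, V{V.shape}"
        )
    d_k = Q.shape[1]
    scores = Q @ K.T / np.sqrt(d_k)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != scores.shape:
            raise ValueError(f"mask shape {mask.shape} != scores shape {scores.shape}")
        if (~mask).all(axis=1).any():
            raise ValueError("attention row with every position masked")
        scores = np.where(mask, scores, _MASK_BIAS)
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=1, keepdims=True)
    return w @ V


@dataclass
class AttentionParams:
    """Per-head projections W_Q[i], W_K[i], W_V[i] and the output projection W_O."""

    W_Q: list
    W_K: list
    W_V: list
    W_O: np.ndarray

    @property
    def n_heads(self) -> int:
        return len(self.W_Q)


def multihead_attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    params: AttentionParams,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Concat(head_1..head_h) W_O with head_i = Attention(Q W_Q[i], K W_K[i], V W_V[i])."""
    h = params.n_heads
    if not (len(params.W_K) == len(params.W_V) == h):
        raise ValueError("per-head weight lists must have equal length")
    heads = []
    for i in range(h):
        heads.append(
            scaled_dot_product_attention(Q @ params.W_Q[i], K @ params.W_K[i], V @ params.W_V[i], mask)
        )
    concat = np.concatenate(heads, axis=1)
    W_O = np.asarray(params.W_O)
    if concat.shape[1] != W_O.shape[0]:
        raise ValueError(
            f"concatenated head width {concat.shape[1]} != W_O rows {W_O.shape[0]}"
        )
    return concat @ W_O


def noam_learning_rate(step: int, d_model: int, warmup_steps: int, scale: float = 1.0) -> float:
    """Inverse-square-root schedule with linear warmup."""
    step = max(int(step), 1)
    return scale * d_model ** -0.5 * min(step ** -0.5, step * warmup_steps ** -1.5)


@dataclass
class ContextMatrix:
    """Encoder output z for one protein: (length, d_model) plus its mask."""

    z: np.ndarray
    source_mask: np.ndarray


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)


class Transformer:
    """The protein-to-SMILES encoder-decoder model.

    Parameters live in ``self.params`` (name -> autograd Tensor).  Source
    and target embeddings are untied; attention projections are stored
    packed as (d_model, d_model) matrices and split into heads on the fly,
    which is algebraically identical to per-head projection matrices.
    """

    def __init__(self, config: ModelConfig, vocab_size: int, seed: int = 0):
        self.config = config
        self.vocab_size = int(vocab_size)
        self.pe = positional_encoding(
            max(config.max_source_len, config.max_target_len + 2),
            config.d_model,
            config.pe_base,
        ).PE
        rng = np.random.default_rng(seed)
        d, dff, L = config.d_model, config.d_ff, config.n_layers
        p: dict[str, ag.Tensor] = {}
        p["src_embed"] = ag.parameter((rng.standard_normal((vocab_size, d)) * d**-0.5).astype(np.float32))
        p["tgt_embed"] = ag.parameter((rng.standard_normal((vocab_size, d)) * d**-0.5).astype(np.float32))

        def attn_block(prefix: str) -> None:
            for w in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{prefix}_{w}"] = ag.parameter(_glorot(rng, d, d))

        def ln_block(prefix: str) -> None:
            p[f"{prefix}_g"] = ag.parameter(np.ones(d, dtype=np.float32))
            p[f"{prefix}_b"] = ag.parameter(np.zeros(d, dtype=np.float32))

        def ff_block(prefix: str) -> None:
            p[f"{prefix}_W1"] = ag.parameter(_glorot(rng, d, dff))
            p[f"{prefix}_b1"] = ag.parameter(np.zeros(dff, dtype=np.float32))
            p[f"{prefix}_W2"] = ag.parameter(_glorot(rng, dff, d))
            p[f"{prefix}_b2"] = ag.parameter(np.zeros(d, dtype=np.float32))

        for i in range(L):
            attn_block(f"enc{i}_self")
            ln_block(f"enc{i}_ln1")
            ff_block(f"enc{i}_ff")
            ln_block(f"enc{i}_ln2")
            attn_block(f"dec{i}_self")
            ln_block(f"dec{i}_ln1")
            attn_block(f"dec{i}_cross")
            ln_block(f"dec{i}_ln2")
            ff_block(f"dec{i}_ff")
            ln_block(f"dec{i}_ln3")
        p["out_W"] = ag.parameter(_glorot(rng, d, vocab_size))
        p["out_b"] = ag.parameter(np.zeros(vocab_size, dtype=np.float32))
        self.params = p

    # ------------------------------------------------------------------ #

    @staticmethod
    def _project(x: ag.Tensor, w: ag.Tensor) -> ag.Tensor:
        """(B, L, d) @ (d, k) via one 2-D GEMM (NumPy's batched matmul on
        3-D operands falls off the single-GEMM fast path)."""
        b, l, d = x.shape
        y = ag.matmul(ag.reshape(x, (b * l, d)), w)
        return ag.reshape(y, (b, l, w.shape[1]))

    def _split_heads(self, x: ag.Tensor, batch: int, length: int) -> ag.Tensor:
        h, dk = self.config.n_heads, self.config.d_k
        x = ag.reshape(x, (batch, length, h, dk))
        return ag.transpose(x, (0, 2, 1, 3))  # (B, h, L, dk)

    def _merge_heads(self, x: ag.Tensor, batch: int, length: int) -> ag.Tensor:
        x = ag.transpose(x, (0, 2, 1, 3))
        return ag.reshape(x, (batch, length, self.config.d_model))

    def _mha(
        self,
        prefix: str,
        x_q: ag.Tensor,
        x_kv: ag.Tensor,
        bias: np.ndarray,
        rng: np.random.Generator | None,
    ) -> ag.Tensor:
        p = self.params
        bq, lq = x_q.shape[0], x_q.shape[1]
        lk = x_kv.shape[1]
        q = self._split_heads(self._project(x_q, p[f"{prefix}_Wq"]), bq, lq)
        k = self._split_heads(self._project(x_kv, p[f"{prefix}_Wk"]), bq, lk)
        v = self._split_heads(self._project(x_kv, p[f"{prefix}_Wv"]), bq, lk)
        scores = ag.mul(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(self.config.d_k))
        w = ag.softmax(scores, bias)  # bias broadcasts over heads
        w = ag.dropout(w, self.config.dropout, rng)
        out = ag.matmul(w, v)
        out = self._merge_heads(out, bq, lq)
        return self._project(out, p[f"{prefix}_Wo"])

    def _ff(self, prefix: str, x: ag.Tensor, rng) -> ag.Tensor:
        p = self.params
        h = ag.relu(ag.add(self._project(x, p[f"{prefix}_W1"]), p[f"{prefix}_b1"]))
        h = ag.dropout(h, self.config.dropout, rng)
        return ag.add(self._project(h, p[f"{prefix}_W2"]), p[f"{prefix}_b2"])

    def _ln(self, prefix: str, x: ag.Tensor) -> ag.Tensor:
        return ag.layer_norm(x, self.params[f"{prefix}_g"], self.params[f"{prefix}_b"])

    def _embed(self, table: str, ids: np.ndarray, rng) -> ag.Tensor:
        d = self.config.d_model
        x = ag.embedding(self.params[table], ids)
        x = ag.mul(x, np.float32(np.sqrt(d)))
        x = ag.add(x, ag.constant(self.pe[None, : ids.shape[1], :]))
        return ag.dropout(x, self.config.dropout, rng)

    @staticmethod
    def _pad_bias(mask: np.ndarray) -> np.ndarray | None:
        # (B, Lk) keep-mask -> additive bias (B, 1, 1, Lk); None when
        # nothing is padded (saves a broadcast add over the score tensor)
        if mask.all():
            return None
        return np.where(mask[:, None, None, :], 0.0, _MASK_BIAS).astype(np.float32)

    def _encoder_stack(self, src_ids: np.ndarray, src_mask: np.ndarray, rng) -> ag.Tensor:
        cfg = self.config
        if src_ids.shape[1] > cfg.max_source_len:
            raise ValueError(f"source length {src_ids.shape[1]} exceeds max {cfg.max_source_len}")
        bias = self._pad_bias(src_mask)
        x = self._embed("src_embed", src_ids, rng)
        for i in range(cfg.n_layers):
            a = self._mha(f"enc{i}_self", x, x, bias, rng)
            x = self._ln(f"enc{i}_ln1", ag.add(x, ag.dropout(a, cfg.dropout, rng)))
            f = self._ff(f"enc{i}_ff", x, rng)
            x = self._ln(f"enc{i}_ln2", ag.add(x, ag.dropout(f, cfg.dropout, rng)))
        return x

    def _decoder_stack(
        self,
        tgt_ids: np.ndarray,
        tgt_mask: np.ndarray,
        memory: ag.Tensor,
        src_mask: np.ndarray,
        rng,
    ) -> ag.Tensor:
        cfg = self.config
        lt = tgt_ids.shape[1]
        if lt > cfg.max_target_len + 2:
            raise ValueError(f"target length {lt} exceeds max {cfg.max_target_len + 2}")
        causal = np.triu(np.full((lt, lt), _MASK_BIAS, dtype=np.float32), k=1)[None, None]
        pad_bias = self._pad_bias(tgt_mask)
        self_bias = causal if pad_bias is None else causal + pad_bias
        cross_bias = self._pad_bias(src_mask)
        x = self._embed("tgt_embed", tgt_ids, rng)
        for i in range(cfg.n_layers):
            a = self._mha(f"dec{i}_self", x, x, self_bias, rng)
            x = self._ln(f"dec{i}_ln1", ag.add(x, ag.dropout(a, cfg.dropout, rng)))
            c = self._mha(f"dec{i}_cross", x, memory, cross_bias, rng)
            x = self._ln(f"dec{i}_ln2", ag.add(x, ag.dropout(c, cfg.dropout, rng)))
            f = self._ff(f"dec{i}_ff", x, rng)
            x = self._ln(f"dec{i}_ln3", ag.add(x, ag.dropout(f, cfg.dropout, rng)))
        return x

    def _logits(self, dec_out: ag.Tensor) -> ag.Tensor:
        return ag.add(self._project(dec_out, self.params["out_W"]), self.params["out_b"])

    # ------------------------------ public ---------------------------- #

    def loss(
        self,
        src_ids: np.ndarray,
        src_mask: np.ndarray,
        tgt_ids: np.ndarray,
        tgt_mask: np.ndarray,
        rng: np.random.Generator | None,
        label_smoothing: float | None = None,
    ) -> ag.Tensor:
        """Teacher-forced label-smoothed cross-entropy on next-token prediction.

        ``label_smoothing=None`` uses the model configuration's value; the
        training loop may override it (e.g. to anneal smoothing to zero).
        """
        dec_in, labels = tgt_ids[:, :-1], tgt_ids[:, 1:]
        dec_in_mask, label_mask = tgt_mask[:, :-1], tgt_mask[:, 1:]
        memory = self._encoder_stack(src_ids, src_mask, rng)
        out = self._decoder_stack(dec_in, dec_in_mask, memory, src_mask, rng)
        logits = self._logits(out)
        ls = self.config.label_smoothing if label_smoothing is None else label_smoothing
        return ag.cross_entropy(logits, labels, label_mask, ls)

    def encoder_forward(self, src_ids: np.ndarray, src_mask: np.ndarray) -> list[ContextMatrix]:
        """Encode a padded source batch into per-protein context matrices z."""
        x = self._encoder_stack(src_ids, src_mask, rng=None)
        return [
            ContextMatrix(z=row[m], source_mask=m[m]) for row, m in zip(x.data, src_mask)
        ]

    def encode_memory(self, src_ids: np.ndarray, src_mask: np.ndarray) -> np.ndarray:
        """Padded encoder output (B, Ls, d_model) for decoding."""
        return self._encoder_stack(src_ids, src_mask, rng=None).data

    def decoder_forward(
        self,
        tgt_prefix: np.ndarray,
        memory: np.ndarray,
        src_mask: np.ndarray,
        tgt_mask: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-position probability rows over the vocabulary, (B, Lt, V).

        The causal mask guarantees position t depends only on prefix tokens
        <= t, so appending a token never changes earlier rows.
        """
        tgt_prefix = np.asarray(tgt_prefix, dtype=np.int64)
        if tgt_prefix.shape[0] != memory.shape[0]:
            raise ValueError("prefix batch and context batch sizes differ")
        if tgt_mask is None:
            tgt_mask = np.ones(tgt_prefix.shape, dtype=bool)
        out = self._decoder_stack(tgt_prefix, tgt_mask, ag.constant(memory), src_mask, rng=None)
        logits = self._logits(out).data.astype(np.float64)
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=-1, keepdims=True)

    def next_token_logprobs(
        self, tgt_prefix: np.ndarray, memory: np.ndarray, src_mask: np.ndarray
    ) -> np.ndarray:
        """Log-probabilities of the token following each prefix, (B, V)."""
        probs = self.decoder_forward(tgt_prefix, memory, src_mask)
        return np.log(np.maximum(probs[:, -1, :], 1e-300))

    # ------------------------------ weights --------------------------- #

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data for k, v in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            # fresh copy: arrays decoded from a checkpoint may sit on an
            # unaligned byte buffer, and BLAS rounding depends on alignment
            v.data = np.array(arrays[k], dtype=v.data.dtype).reshape(v.data.shape)
            v.grad = None


# ---------------------------------------------------------------------- #
#  training
# ---------------------------------------------------------------------- #


def _encode_pairs(pairs, vocab: Vocabulary) -> list[tuple[TokenSequence, TokenSequence]]:
    return [
        (encode(p, vocab, "source"), encode(s, vocab, "target")) for p, s in pairs
    ]


def _epoch_batches(encoded, batch_tokens: int, seed: int, epoch: int) -> list[list[int]]:
    """Random length-mixed batches of ~``batch_tokens`` tokens for one epoch.

    Pairs are shuffled (a pure function of seed and epoch, so resumed runs
    reproduce the order) and chunked greedily by padded token count.
    Mixing target lengths within a batch keeps every gradient step exposed
    to all motif-count regimes; length-sorted bucketing gave each step a
    single regime and measurably slowed generalization.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE90C, epoch]))
    order = rng.permutation(len(encoded))
    batches: list[list[int]] = []
    cur: list[int] = []
    max_s = max_t = 0
    for i in order:
        s, t = encoded[int(i)]
        ns, nt = max(max_s, s.length), max(max_t, t.length)
        if cur and (len(cur) + 1) * (ns + nt) > batch_tokens:
            batches.append(cur)
            cur, ns, nt = [], s.length, t.length
        cur.append(int(i))
        max_s, max_t = ns, nt
    if cur:
        batches.append(cur)
    return batches


def _batch_arrays(encoded, idxs, pad_id=0):
    srcs = [encoded[i][0] for i in idxs]
    tgts = [encoded[i][1] for i in idxs]
    src_ids, src_mask = pad_batch(srcs, pad_id=pad_id)
    tgt_ids, tgt_mask = pad_batch(tgts, pad_id=pad_id)
    return src_ids, src_mask, tgt_ids, tgt_mask


class _Adam:
    def __init__(self, params: dict, cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, lr: float) -> None:
        c = self.cfg
        self.t += 1
        # global-norm gradient clipping; keep every scalar a python float so
        # float32 parameters are never promoted to float64
        total = 0.0
        for p in params.values():
            if p.grad is not None:
                g = p.grad.ravel()
                total += float(np.dot(g, g))
        norm = float(np.sqrt(total))
        scale = 1.0 if norm <= c.grad_clip else float(c.grad_clip / (norm + 1e-12))
        bc1 = 1.0 - c.adam_beta1**self.t
        bc2 = 1.0 - c.adam_beta2**self.t
        for k, p in params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * g
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * g * g
            if c.weight_decay:
                p.data *= 1.0 - lr * c.weight_decay
            p.data -= (lr / bc1) * self.m[k] / (np.sqrt(self.v[k] / bc2) + c.adam_eps)
            p.grad = None


def train_model(
    pairs,
    vocab: Vocabulary,
    config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    resume_from=None,
    log_fn=None,
) -> tuple[Transformer, TrainState]:
    """Train the transformer on (protein, SMILES) pairs.

    Deterministic under fixed ``seed``: weight initialization, batch order
    and dropout all derive from it.  ``resume_from`` restores a checkpoint
    (weights, optimizer moments, dropout RNG, step counter) and continues,
    reproducing the uninterrupted trajectory.  Raises
    :class:`TrainingDivergedError` on non-finite loss.
    """
    config = config or ModelConfig()
    tc = train_config or TrainConfig()
    encoded = _encode_pairs(pairs, vocab)

    model = Transformer(config, len(vocab), seed=seed)
    opt = _Adam(model.params, tc)
    drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD06]))
    start_step = 0
    state = TrainState(seed=seed)

    if resume_from is not None:
        arrays, meta = _read_checkpoint(resume_from)
        if meta["vocab_hash"] != vocab.content_hash():
            raise CheckpointMismatchError(
                "checkpoint vocabulary hash does not match the current vocabulary"
            )
        model.load_state_arrays({k[2:]: v for k, v in arrays.items() if k.startswith("w:")})
        for k in opt.m:
            opt.m[k] = np.array(arrays[f"m:{k}"])
            opt.v[k] = np.array(arrays[f"v:{k}"])
        opt.t = meta["adam_t"]
        start_step = meta["step"]
        drop_rng.bit_generator.state = meta["dropout_rng_state"]
        state.log = [tuple(r) for r in meta.get("log", [])]

    use_dropout = config.dropout > 0.0
    # the computation graph is a DAG freed by reference counting alone;
    # cyclic GC only adds per-step scans of the growing closure graph
    import gc

    gc_was_enabled = gc.isenabled()
    gc.disable()
    try:
        _train_loop(
            model, opt, encoded, vocab, config, tc, seed,
            start_step, drop_rng if use_dropout else None, state, log_fn,
        )
    finally:
        if gc_was_enabled:
            gc.enable()
    if tc.average_last > 0 and model._snapshots:
        # checkpoint averaging over the tail of training
        snaps = model._snapshots[-tc.average_last :]
        for k, p in model.params.items():
            p.data = np.mean([s[k] for s in snaps] + [p.data], axis=0).astype(p.data.dtype)
        model._snapshots = []
    model._opt = opt  # kept for checkpointing
    model._drop_rng = drop_rng
    return model, state


def _train_loop(model, opt, encoded, vocab, config, tc, seed,
                start_step, drop_rng, state, log_fn):
    model._snapshots = []
    # batches are recomposed per epoch as a pure function of (seed, epoch),
    # so a resumed run fast-forwards to the identical position
    epoch = 0
    batches = _epoch_batches(encoded, tc.batch_tokens, seed, epoch)
    pos = 0
    for _ in range(start_step):
        pos += 1
        if pos >= len(batches):
            epoch += 1
            batches = _epoch_batches(encoded, tc.batch_tokens, seed, epoch)
            pos = 0
    for step in range(start_step + 1, tc.steps + 1):
        src_ids, src_mask, tgt_ids, tgt_mask = _batch_arrays(
            encoded, batches[pos], pad_id=vocab.pad_id
        )
        pos += 1
        if pos >= len(batches):
            epoch += 1
            batches = _epoch_batches(encoded, tc.batch_tokens, seed, epoch)
            pos = 0
        ls = None
        if tc.plain_ce_after is not None and step > tc.plain_ce_after:
            ls = 0.0
        loss = model.loss(src_ids, src_mask, tgt_ids, tgt_mask, drop_rng, label_smoothing=ls)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise TrainingDivergedError(f"non-finite loss {loss_val} at step {step}")
        loss.backward()
        lr = noam_learning_rate(step, config.d_model, tc.warmup_steps, tc.lr_scale)
        opt.step(model.params, lr)
        state.step, state.learning_rate, state.loss = step, lr, loss_val
        if tc.average_last > 0 and step % tc.snapshot_every == 0:
            model._snapshots.append({k: p.data.copy() for k, p in model.params.items()})
            model._snapshots = model._snapshots[-tc.average_last :]
        if step % tc.log_every == 0 or step == 1 or step == tc.steps:
            state.log.append((step, lr, loss_val))
            if log_fn is not None:
                log_fn(step, lr, loss_val)


# ---------------------------------------------------------------------- #
#  checkpoints
# ---------------------------------------------------------------------- #


def save_checkpoint(path, model: Transformer, vocab: Vocabulary, state: TrainState) -> None:
    """Serialize weights + config + vocabulary hash (+ optimizer for resume)."""
    arrays = {f"w:{k}": v for k, v in model.state_arrays().items()}
    opt = getattr(model, "_opt", None)
    meta = {
        "format": "prot2drug-checkpoint-v1",
        "config": asdict(model.config),
        "vocab_hash": vocab.content_hash(),
        "vocab_tokens": [vocab.id_to_token[i] for i in range(len(vocab))],
        "step": state.step,
        "seed": state.seed,
        "log": [list(r) for r in state.log],
        "adam_t": opt.t if opt else 0,
        "dropout_rng_state": getattr(model, "_drop_rng", np.random.default_rng()).bit_generator.state,
    }
    if opt is not None:
        for k in opt.m:
            arrays[f"m:{k}"] = opt.m[k]
            arrays[f"v:{k}"] = opt.v[k]
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with open(path, "wb") as fh:
        header = json.dumps(meta, default=_json_default).encode()
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        fh.write(zlib.compress(buf.getvalue(), level=1))


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    raise TypeError(type(o))


def _read_checkpoint(path):
    with open(path, "rb") as fh:
        n = int.from_bytes(fh.read(8), "little")
        meta = json.loads(fh.read(n).decode())
        arrays = dict(np.load(io.BytesIO(zlib.decompress(fh.read()))))
    return arrays, meta


def load_checkpoint(path) -> tuple[Transformer, Vocabulary, dict]:
    """Rebuild model + vocabulary from a checkpoint file."""
    arrays, meta = _read_checkpoint(path)
    tokens = meta["vocab_tokens"]
    vocab = Vocabulary(
        token_to_id={t: i for i, t in enumerate(tokens)},
        id_to_token=dict(enumerate(tokens)),
    )
    config = ModelConfig(**meta["config"])
    model = Transformer(config, len(vocab), seed=meta.get("seed", 0))
    model.load_state_arrays({k[2:]: v for k, v in arrays.items() if k.startswith("w:")})
    return model, vocab, meta
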