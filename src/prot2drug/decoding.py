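"""Beam-search decoding of SMILES strings from a protein context.

At each step every live hypothesis is extended by every vocabulary token
and exactly the ``beam_size`` extensions with the highest cumulative
log-probability survive; a hypothesis ends when it emits EOS or reaches
``max_len``.  With beam size 1 this is greedy search.  Two generation
modes mirror the intended use: ``one_per_one`` runs beam size 4 and keeps
only the single best SMILES per protein; ``ten_per_one`` runs beam size 10
and keeps all ten candidates.

Scores are raw summed log-probabilities by default; an optional GNMT-style
length penalty ``alpha`` divides them by ((5 + len) / 6) ** alpha.  Ties
are broken toward lower token ids, making decoding fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .model import Transformer
from .tokenizer import Vocabulary, decode, encode, pad_batch

__all__ = ["Beam", "GenerationResult", "beam_search", "beam_search_model", "greedy_decode_batch", "generate"]


@dataclass
class Beam:
    """Finished hypotheses, sorted by score descending: (token ids, log-prob)."""

    hypotheses: list
    width: int


@dataclass
class GenerationResult:
    """Ranked decoded SMILES for one target protein."""

    protein_id: str
    candidates: list  # (smiles, log_prob), scores nonincreasing
    mode: Literal["one_per_one", "ten_per_one"]


def _length_penalty(length: int, alpha: float) -> float:
    if alpha == 0.0:
        return 1.0
    return ((5.0 + length) / 6.0) ** alpha


def beam_search(
    step_fn: Callable[[list], np.ndarray],
    bos_id: int,
    eos_id: int,
    beam_size: int,
    max_len: int,
    length_penalty: float = 0.0,
) -> Beam:
    """Generic beam search over an autoregressive next-token model.

    ``step_fn(prefixes)`` takes a list of token-id lists (each starting
    with BOS) and returns an (n, V) array of next-token log-probabilities.
    ``max_len`` bounds the number of generated tokens (EOS included).
    Returns up to ``beam_size`` finished hypotheses; the ids exclude BOS
    but include EOS when one was emitted.
    """
    if beam_size < 1:
        raise ValueError("beam_size must be >= 1")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")

    live: list[tuple[tuple[int, ...], float]] = [((bos_id,), 0.0)]
    finished: list[tuple[tuple[int, ...], float]] = []
    for _ in range(max_len):
        if not live:
            break
        logp = np.asarray(step_fn([list(h) for h, _ in live]), dtype=np.float64)
        cand: list[tuple[float, tuple[int, ...]]] = []
        for (hyp, score), row in zip(live, logp):
            for tok in range(row.shape[0]):
                cand.append((score + float(row[tok]), hyp + (tok,)))
        # top beam_size by score; ties toward lower token ids (tuple order)
        cand.sort(key=lambda c: (-c[0], c[1]))
        cand = cand[:beam_size]
        live = []
        for score, hyp in cand:
            if hyp[-1] == eos_id:
                finished.append((hyp, score))
            else:
                live.append((hyp, score))
        # sound stopping: raw scores only decrease with extension, so once
        # the best live hypothesis cannot beat the current top-k finished
        # ones nothing better can appear (stopping merely at "k finished"
        # would bias the result toward short early-EOS hypotheses)
        if len(finished) >= beam_size:
            finished.sort(key=lambda f: (-f[1], f[0]))
            finished = finished[: beam_size + len(live)]
            if not live or live[0][1] <= finished[beam_size - 1][1]:
                break
    # hypotheses that never emitted EOS are closed at max_len
    finished.extend(live)
    ranked = sorted(
        finished,
        key=lambda f: (-f[1] / _length_penalty(len(f[0]) - 1, length_penalty), f[0]),
    )[:beam_size]
    return Beam(
        hypotheses=[(list(h[1:]), s) for h, s in ranked],
        width=beam_size,
    )


def beam_search_model(
    model: Transformer,
    memory: np.ndarray,
    src_mask: np.ndarray,
    vocab: Vocabulary,
    beam_size: int,
    max_len: int | None = None,
    length_penalty: float = 0.0,
) -> Beam:
    """Beam search against a trained transformer for one encoded protein.

    ``memory`` is the encoder output for a single protein, shape
    (1, Ls, d_model); the beam batch is run through the decoder jointly.
    PAD can never be emitted: its log-probability is forced to -inf.
    """
    if max_len is None:
        max_len = model.config.max_target_len + 2

    def step_fn(prefixes: list) -> np.ndarray:
        n = len(prefixes)
        mem = np.repeat(memory, n, axis=0)
        msk = np.repeat(src_mask, n, axis=0)
        width = max(len(p) for p in prefixes)
        ids = np.full((n, width), vocab.pad_id, dtype=np.int64)
        pmask = np.zeros((n, width), dtype=bool)
        for i, p in enumerate(prefixes):
            ids[i, : len(p)] = p
            pmask[i, : len(p)] = True
        logp = model.next_token_logprobs(ids, mem, msk)
        logp[:, vocab.pad_id] = -np.inf
        return logp

    return beam_search(step_fn, vocab.bos_id, vocab.eos_id, beam_size, max_len, length_penalty)


def greedy_decode_batch(
    model: Transformer,
    proteins: list,
    vocab: Vocabulary,
    max_len: int | None = None,
) -> list:
    """Greedy (beam-1) decoding of a whole protein batch at once.

    Returns one SMILES string per protein.  Equivalent to per-protein beam
    search with beam size 1 but runs the decoder on the full batch, which
    is the fast path for held-out evaluation.
    """
    if max_len is None:
        max_len = model.config.max_target_len + 2
    srcs = [encode(p, vocab, "source") for p in proteins]
    src_ids, src_mask = pad_batch(srcs, pad_id=vocab.pad_id)
    memory = model.encode_memory(src_ids, src_mask)
    n = len(proteins)
    prefixes = np.full((n, 1), vocab.bos_id, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    for _ in range(max_len):
        logp = model.next_token_logprobs(prefixes, memory, src_mask)
        logp[:, vocab.pad_id] = -np.inf
        nxt = logp.argmax(axis=1)
        nxt[done] = vocab.pad_id
        prefixes = np.concatenate([prefixes, nxt[:, None]], axis=1)
        done |= nxt == vocab.eos_id
        if done.all():
            break
    return [decode(row, vocab) for row in prefixes]


def generate(
    protein: str,
    model: Transformer,
    vocab: Vocabulary,
    mode: Literal["one_per_one", "ten_per_one"] = "one_per_one",
    protein_id: str = "",
    length_penalty: float = 0.0,
) -> GenerationResult:
    """Generate SMILES candidates for one protein sequence.

    ``one_per_one`` keeps the top hypothesis of a beam-4 search;
    ``ten_per_one`` keeps all candidates of a beam-10 search.  Candidates
    are detokenized (specials stripped) and deduplicated as strings,
    keeping the best-scoring occurrence.
    """
    if mode not in ("one_per_one", "ten_per_one"):
        raise ValueError(f"unknown mode {mode!r}")
    beam_size = 4 if mode == "one_per_one" else 10
    keep = 1 if mode == "one_per_one" else 10
    src = encode(protein, vocab, "source")
    if src.length > model.config.max_source_len:
        raise ValueError("protein longer than the model's maximum source length")
    src_ids = src.ids[None, :]
    src_mask = np.ones_like(src_ids, dtype=bool)
    memory = model.encode_memory(src_ids, src_mask)
    beam = beam_search_model(model, memory, src_mask, vocab, beam_size)
    # a hypothesis that hit the length cap without emitting EOS is not a
    # completed molecule; keep it only if nothing finished at all
    finished = [(ids, s) for ids, s in beam.hypotheses if ids and ids[-1] == vocab.eos_id]
    hypotheses = finished or beam.hypotheses
    seen: dict[str, float] = {}
    ordered: list[str] = []
    for ids, score in hypotheses:
        smiles = decode(np.asarray(ids), vocab)
        if smiles not in seen:
            seen[smiles] = score
            ordered.append(smiles)
    candidates = [(s, seen[s]) for s in ordered][:keep]
    return GenerationResult(protein_id=protein_id or protein[:12], candidates=candidates, mode=mode)
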