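"""Independent brute-force oracles used by the test suite.

Each oracle is written as plainly as possible — per-element loops, direct
recurrences, exhaustive enumeration — and deliberately shares no code with
the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

NEG = float("-inf")


def attention_rowloop(Q, K, V, mask=None):
    """Scaled dot-product attention computed one query row at a time."""
    Q, K, V = np.asarray(Q, float), np.asarray(K, float), np.asarray(V, float)
    m, d_k = Q.shape
    n, d_v = V.shape
    out = np.zeros((m, d_v))
    for i in range(m):
        scores = []
        for j in range(n):
            s = sum(Q[i, t] * K[j, t] for t in range(d_k)) / math.sqrt(d_k)
            if mask is not None and not mask[i, j]:
                s = NEG
            scores.append(s)
        mx = max(scores)
        w = [math.exp(s - mx) for s in scores]
        z = sum(w)
        for j in range(n):
            for t in range(d_v):
                out[i, t] += (w[j] / z) * V[j, t]
    return out


def multihead_rowloop(Q, K, V, W_Q, W_K, W_V, W_O, mask=None):
    """Multihead attention: each head independently, then concat + project."""
    heads = [
        attention_rowloop(
            np.asarray(Q) @ np.asarray(wq),
            np.asarray(K) @ np.asarray(wk),
            np.asarray(V) @ np.asarray(wv),
            mask,
        )
        for wq, wk, wv in zip(W_Q, W_K, W_V)
    ]
    return np.concatenate(heads, axis=1) @ np.asarray(W_O)


def gotoh_plain(a, b, sub_lookup, gap_open, gap_extend, free_ends=True):
    """Plain three-state affine-gap global alignment (Gotoh).

    ``sub_lookup(x, y)`` returns the substitution score of residues x, y.
    Returns (score, identity_pct, alignment_length).  Gap of length L
    costs open + (L-1)*extend; tie preference M > gap-in-b > gap-in-a.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    pM = [[0] * (m + 1) for _ in range(n + 1)]
    pX = [[0] * (m + 1) for _ in range(n + 1)]
    pY = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0 if free_ends else -(gap_open + (i - 1) * gap_extend)
        pX[i][0] = 1
    for j in range(1, m + 1):
        Y[0][j] = 0.0 if free_ends else -(gap_open + (j - 1) * gap_extend)
        pY[0][j] = 2

    def argmax3(vals):
        best, ptr = vals[0], 0
        for s, v in enumerate(vals[1:], start=1):
            if v > best:
                best, ptr = v, s
        return best, ptr

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best, ptr = argmax3([M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]])
            M[i][j] = best + sub_lookup(a[i - 1], b[j - 1])
            pM[i][j] = ptr
            best, ptr = argmax3(
                [M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend, Y[i - 1][j] - gap_open]
            )
            X[i][j], pX[i][j] = best, ptr
            best, ptr = argmax3(
                [M[i][j - 1] - gap_open, X[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend]
            )
            Y[i][j], pY[i][j] = best, ptr

    candidates = [(M[n][m], n, m, 0), (X[n][m], n, m, 1), (Y[n][m], n, m, 2)]
    if free_ends:
        for i in range(n - 1, -1, -1):
            for s, mat in enumerate((M, X, Y)):
                candidates.append((mat[i][m], i, m, s))
        for j in range(m - 1, -1, -1):
            for s, mat in enumerate((M, X, Y)):
                candidates.append((mat[n][j], n, j, s))
    score, bi, bj, state = candidates[0]
    for c in candidates[1:]:
        if c[0] > score:
            score, bi, bj, state = c

    aln_len = (n - bi) + (m - bj)
    ident = 0
    i, j = bi, bj
    while i > 0 or j > 0:
        aln_len += 1
        if state == 0:
            if a[i - 1] == b[j - 1]:
                ident += 1
            state = pM[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            state = pX[i][j]
            i -= 1
            if i == 0 and j > 0:
                state = 2
        else:
            state = pY[i][j]
            j -= 1
            if j == 0 and i > 0:
                state = 1
    return score, 100.0 * ident / aln_len, aln_len


def enumerate_sequences(logprob_fn, vocab_size, eos_id, max_len):
    """All decision sequences of an autoregressive model, exhaustively scored.

    A sequence terminates at EOS or at ``max_len`` tokens.  Returns
    [(token tuple, total log-prob)] sorted by score descending, ties toward
    lexicographically smaller sequences.
    """
    results = []

    def walk(prefix, score):
        if prefix and (prefix[-1] == eos_id or len(prefix) == max_len):
            results.append((prefix, score))
            return
        row = logprob_fn(prefix)
        for tok in range(vocab_size):
            walk(prefix + (tok,), score + float(row[tok]))

    walk((), 0.0)
    return sorted(results, key=lambda r: (-r[1], r[0]))


def auc_pair_count(pos, neg):
    """AUC by counting all n1*n2 pairs, half credit for ties."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
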