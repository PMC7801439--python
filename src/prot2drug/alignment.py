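"""Global protein sequence alignment and percent identity.

Percent identity between proteins drives the similarity-constrained
train/test splitting: a candidate test protein may not exceed a given
identity with any training protein.  Identity is computed from a full
Needleman-Wunsch global alignment with affine gap costs (Gotoh's three-state
dynamic program), using BLOSUM62 with gap open 10.0 / extend 0.5 and free
terminal gaps — the defaults of the EMBOSS ``needle`` tool.  Percent
identity is identical aligned positions over the full alignment length
(terminal gap columns included), times 100; percent similarity counts
positive-scoring substitutions instead.

Tie-breaking among co-optimal alignments is deterministic (match state
preferred over a gap in the second sequence, preferred over a gap in the
first), and the public functions order their two arguments canonically so
that identity is exactly symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentConfig",
    "AlignmentInputError",
    "IdentityMatrix",
    "pairwise_identity",
    "pairwise_similarity",
    "align_stats",
    "identity_matrix",
]

_NEG = -1e30


class AlignmentInputError(ValueError):
    """Raised for sequences containing residues outside the matrix alphabet."""


def _load_matrix(name: str) -> tuple[str, np.ndarray]:
    m = substitution_matrices.load(name)
    alphabet = str(m.alphabet)
    arr = np.asarray(m, dtype=np.float64)
    return alphabet, arr


@dataclass
class AlignmentConfig:
    """Parameters of the global alignment (EMBOSS needle protein defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    free_end_gaps: bool = True
    _cache: tuple[str, np.ndarray] | None = field(default=None, repr=False, compare=False)

    def matrix_data(self) -> tuple[str, np.ndarray]:
        if self._cache is None:
            self._cache = _load_matrix(self.matrix)
        return self._cache


def _encode(seq: str, alphabet: str, which: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        j = alphabet.find(ch.upper())
        if j < 0:
            raise AlignmentInputError(
                f"illegal residue {ch!r} at position {i + 1} of sequence {which}"
            )
        out[i] = j
    return out


def _gotoh(a, b, sub, gap_open, gap_extend, free_ends):  # pragma: no cover - jit
    """Three-state affine-gap DP with traceback.

    Returns (score, n_identity, n_similar, alignment_length).  States:
    0 = M (substitution), 1 = X (gap in b, consumes a), 2 = Y (gap in a,
    consumes b).  A gap of length L costs open + (L - 1) * extend.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if free_ends else -(gap_open + (i - 1) * gap_extend)
        pX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if free_ends else -(gap_open + (j - 1) * gap_extend)
        pY[0, j] = 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: preference order M > X > Y on ties
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + sub[a[i - 1], b[j - 1]]
            pM[i, j] = ptr
            # X: gap in b
            best = M[i - 1, j] - gap_open
            ptr = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                ptr = 1
            if Y[i - 1, j] - gap_open > best:
                best = Y[i - 1, j] - gap_open
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr
            # Y: gap in a
            best = M[i, j - 1] - gap_open
            ptr = 0
            if X[i, j - 1] - gap_open > best:
                best = X[i, j - 1] - gap_open
                ptr = 1
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr

    # terminal cell and state
    bi, bj, bstate = n, m, 0
    bscore = M[n, m]
    if X[n, m] > bscore:
        bscore, bstate = X[n, m], 1
    if Y[n, m] > bscore:
        bscore, bstate = Y[n, m], 2
    if free_ends:
        for i in range(n - 1, -1, -1):
            for s in range(3):
                v = M[i, m] if s == 0 else (X[i, m] if s == 1 else Y[i, m])
                if v > bscore:
                    bscore, bi, bj, bstate = v, i, m, s
        for j in range(m - 1, -1, -1):
            for s in range(3):
                v = M[n, j] if s == 0 else (X[n, j] if s == 1 else Y[n, j])
                if v > bscore:
                    bscore, bi, bj, bstate = v, n, j, s

    # trailing free-gap columns
    aln_len = (n - bi) + (m - bj)
    n_id = 0
    n_sim = 0
    i, j, state = bi, bj, bstate
    while i > 0 or j > 0:
        aln_len += 1
        if state == 0:
            if a[i - 1] == b[j - 1]:
                n_id += 1
            if sub[a[i - 1], b[j - 1]] > 0:
                n_sim += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pX[i, j]
            i -= 1
            if i == 0 and j > 0:
                state = 2
        else:
            state = pY[i, j]
            j -= 1
            if j == 0 and i > 0:
                state = 1
    return bscore, n_id, n_sim, aln_len


try:  # numba acceleration for long proteins; identical pure-Python fallback
    from numba import njit

    _gotoh_fast = njit(cache=False, nogil=True)(_gotoh)
except Exception:  # pragma: no cover
    _gotoh_fast = _gotoh


def align_stats(a: str, b: str, config: AlignmentConfig | None = None) -> dict:
    """Align two protein sequences and return score/identity/similarity.

    Returns a dict with keys ``score``, ``identity_pct``, ``similarity_pct``
    and ``alignment_length``.  Arguments are ordered canonically first, so
    results are symmetric in (a, b).
    """
    if not a or not b:
        raise AlignmentInputError("sequences must be non-empty")
    if b < a:
        a, b = b, a
    config = config or AlignmentConfig()
    alphabet, sub = config.matrix_data()
    ea = _encode(a, alphabet, "a")
    eb = _encode(b, alphabet, "b")
    score, n_id, n_sim, aln_len = _gotoh_fast(
        ea, eb, sub, float(config.gap_open), float(config.gap_extend), config.free_end_gaps
    )
    return {
        "score": float(score),
        "identity_pct": 100.0 * n_id / aln_len,
        "similarity_pct": 100.0 * n_sim / aln_len,
        "alignment_length": int(aln_len),
    }


def pairwise_identity(a: str, b: str, config: AlignmentConfig | None = None) -> float:
    """Percent identity in [0, 100] from a global affine-gap alignment."""
    return align_stats(a, b, config)["identity_pct"]


def pairwise_similarity(a: str, b: str, config: AlignmentConfig | None = None) -> float:
    """Percent similarity (positive-scoring aligned pairs) in [0, 100]."""
    return align_stats(a, b, config)["similarity_pct"]


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percent-identity matrix over an ordered sequence list."""

    sequences: list[str]
    identity_pct: np.ndarray

    def __post_init__(self):
        self.identity_pct = np.asarray(self.identity_pct, dtype=np.float64)
        n = len(self.sequences)
        if self.identity_pct.shape != (n, n):
            raise ValueError("identity matrix shape does not match sequence count")

    def lookup(self, a: str, b: str) -> float:
        i = self.sequences.index(a)
        j = self.sequences.index(b)
        return float(self.identity_pct[i, j])


def identity_matrix(
    sequences: list[str], config: AlignmentConfig | None = None
) -> IdentityMatrix:
    """All-vs-all percent identity; diagonal is 100 by definition."""
    config = config or AlignmentConfig()
    n = len(sequences)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(sequences[i], sequences[j], config)
            mat[i, j] = mat[j, i] = pid
    return IdentityMatrix(list(sequences), mat)
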