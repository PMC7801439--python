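"""Character-level tokenization for protein sequences and SMILES strings.

One joint vocabulary covers both "languages": every character occurring in
any protein sequence or SMILES string of the curated dataset becomes a
token, plus three specials (PAD=0, BOS=1, EOS=2).  Tokens are strict single
characters — two-letter element symbols such as Cl or Br are two tokens.
Target (SMILES) sequences are wrapped in BOS...EOS when encoded; source
(protein) sequences are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "Vocabulary",
    "TokenSequence",
    "OutOfVocabularyError",
    "build_vocabulary",
    "encode",
    "decode",
    "pad_batch",
    "unpad_batch",
]

PAD, BOS, EOS = "<pad>", "<bos>", "<eos>"
_SPECIALS = (PAD, BOS, EOS)

# default length caps: proteins bounded by the curation length filter,
# SMILES kept short by the MW < 1000 Da filter
MAX_SOURCE_LEN = 2050
MAX_TARGET_LEN = 200


class OutOfVocabularyError(KeyError):
    def __init__(self, char: str, position: int):
        super().__init__(f"character {char!r} at position {position} not in vocabulary")
        self.char = char
        self.position = position


@dataclass(frozen=True)
class Vocabulary:
    """Bijective symbol<->id maps with PAD/BOS/EOS specials at ids 0..2."""

    token_to_id: dict
    id_to_token: dict

    pad_id: int = 0
    bos_id: int = 1
    eos_id: int = 2

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def n_symbols(self) -> int:
        """Dataset symbols, excluding the three specials."""
        return len(self.token_to_id) - 3

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# prot2drug vocabulary v1: one token per line, id = line order\n")
            for i in range(len(self.id_to_token)):
                fh.write(self.id_to_token[i] + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
        tokens = [ln for ln in lines if ln != ""]
        if tokens[:3] != list(_SPECIALS):
            raise ValueError("vocabulary file does not start with PAD/BOS/EOS specials")
        return cls(
            token_to_id={t: i for i, t in enumerate(tokens)},
            id_to_token=dict(enumerate(tokens)),
        )

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for i in range(len(self.id_to_token)):
            h.update(self.id_to_token[i].encode())
            h.update(b"\x00")
        return h.hexdigest()[:16]


@dataclass
class TokenSequence:
    """Encoded ids of one source or target string."""

    ids: np.ndarray
    kind: Literal["source", "target"]

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)

    @property
    def length(self) -> int:
        return int(self.ids.shape[0])


def build_vocabulary(dataset) -> Vocabulary:
    """Vocabulary of all characters in the dataset's proteins and SMILES.

    ``dataset`` is a :class:`~prot2drug.curation.CuratedDataset` or any
    iterable of strings.  Symbols are sorted, so construction is
    deterministic and permutation-invariant.
    """
    if hasattr(dataset, "records"):
        texts: Iterable[str] = [r.protein_sequence for r in dataset.records] + [
            r.smiles for r in dataset.records
        ]
    else:
        texts = list(dataset)
    symbols: set[str] = set()
    for t in texts:
        symbols.update(t)
    if not symbols:
        raise ValueError("cannot build a vocabulary from an empty dataset")
    tokens = list(_SPECIALS) + sorted(symbols)
    return Vocabulary(
        token_to_id={t: i for i, t in enumerate(tokens)},
        id_to_token=dict(enumerate(tokens)),
    )


def encode(text: str, vocab: Vocabulary, kind: Literal["source", "target"]) -> TokenSequence:
    """Encode a string; target kind wraps the ids in BOS ... EOS."""
    ids = []
    for pos, ch in enumerate(text, start=1):
        i = vocab.token_to_id.get(ch)
        if i is None:
            raise OutOfVocabularyError(ch, pos)
        ids.append(i)
    if kind == "target":
        ids = [vocab.bos_id] + ids + [vocab.eos_id]
    return TokenSequence(np.asarray(ids, dtype=np.int64), kind)


def decode(ids, vocab: Vocabulary) -> str:
    """Inverse of :func:`encode`; specials are stripped."""
    if isinstance(ids, TokenSequence):
        ids = ids.ids
    special = {vocab.pad_id, vocab.bos_id, vocab.eos_id}
    return "".join(vocab.id_to_token[int(i)] for i in ids if int(i) not in special)


def pad_batch(
    seqs: list[TokenSequence], max_len: int | None = None, pad_id: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stack sequences into a (batch, max_len) id matrix + boolean mask.

    The mask is True exactly on real (non-PAD) positions.  Raises
    ``ValueError`` if any sequence exceeds ``max_len``.
    """
    lengths = [s.length for s in seqs]
    if max_len is None:
        max_len = max(lengths)
    too_long = [i for i, n in enumerate(lengths) if n > max_len]
    if too_long:
        raise ValueError(f"sequence {too_long[0]} has length {lengths[too_long[0]]} > max_len {max_len}")
    ids = np.full((len(seqs), max_len), pad_id, dtype=np.int64)
    mask = np.zeros((len(seqs), max_len), dtype=bool)
    for i, s in enumerate(seqs):
        ids[i, : s.length] = s.ids
        mask[i, : s.length] = True
    return ids, mask


def unpad_batch(ids: np.ndarray, mask: np.ndarray, kind="source") -> list[TokenSequence]:
    """Recover the original sequences from :func:`pad_batch` output."""
    return [TokenSequence(row[m], kind) for row, m in zip(ids, mask)]
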