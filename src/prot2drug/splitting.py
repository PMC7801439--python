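"""Similarity-constrained Monte-Carlo train/test splitting of proteins.

A split assigns every unique protein to the training pool, the test pool,
or drops it, such that no test protein shares >= ``identity_threshold_pct``
global-alignment identity with any training protein.  Construction is
greedy over a seeded random order: the first protein seeds the training
pool, later proteins go to the smaller-than-target test pool when they are
compatible with every training protein, otherwise to the training pool when
compatible with every test protein, and are dropped when neither placement
is possible.  Proportions approach 90/10 where the constraint permits.

``verify_split`` re-checks the constraint exhaustively over all
test x train pairs and is used on every emitted split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentConfig, IdentityMatrix, identity_matrix
from .curation import CuratedDataset

__all__ = [
    "SplitSpec",
    "InfeasibleSplitError",
    "build_split",
    "monte_carlo_splits",
    "verify_split",
]


class InfeasibleSplitError(RuntimeError):
    """No nonempty test set can satisfy the identity constraint."""


@dataclass
class SplitSpec:
    """One train/test division of the unique proteins."""

    train_proteins: list[str]
    test_proteins: list[str]
    dropped_proteins: list[str] = field(default_factory=list)
    identity_threshold_pct: float = 20.0
    replicate_index: int = 1
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "identity_threshold_pct": self.identity_threshold_pct,
                "replicate_index": self.replicate_index,
                "seed": self.seed,
                "train_proteins": self.train_proteins,
                "test_proteins": self.test_proteins,
                "dropped_proteins": self.dropped_proteins,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        d = json.loads(text)
        return cls(
            train_proteins=d["train_proteins"],
            test_proteins=d["test_proteins"],
            dropped_proteins=d.get("dropped_proteins", []),
            identity_threshold_pct=d["identity_threshold_pct"],
            replicate_index=d.get("replicate_index", 1),
            seed=d.get("seed", 0),
        )


def _proteins_of(dataset) -> list[str]:
    if isinstance(dataset, CuratedDataset):
        return dataset.unique_proteins
    return list(dataset)


def verify_split(split: SplitSpec, matrix: IdentityMatrix) -> bool:
    """Exhaustively re-check max cross identity < threshold and disjointness."""
    if set(split.train_proteins) & set(split.test_proteins):
        return False
    idx = {s: i for i, s in enumerate(matrix.sequences)}
    for t in split.test_proteins:
        for tr in split.train_proteins:
            if matrix.identity_pct[idx[t], idx[tr]] >= split.identity_threshold_pct:
                return False
    return True


def build_split(
    dataset,
    threshold_pct: float = 20.0,
    seed: int = 0,
    test_fraction: float = 0.1,
    alignment_config: AlignmentConfig | None = None,
    matrix: IdentityMatrix | None = None,
    replicate_index: int = 1,
) -> SplitSpec:
    """Build one similarity-constrained split of the dataset's proteins.

    ``dataset`` may be a :class:`CuratedDataset` or a plain sequence list;
    ``matrix`` may carry precomputed identities (it is computed otherwise).
    Raises :class:`InfeasibleSplitError` when no valid nonempty test set
    exists alongside a nonempty training set.
    """
    proteins = _proteins_of(dataset)
    if len(proteins) < 2:
        raise InfeasibleSplitError("need at least two unique proteins to split")
    if matrix is None:
        matrix = identity_matrix(sorted(proteins), alignment_config)
    idx = {s: i for i, s in enumerate(matrix.sequences)}
    pid = matrix.identity_pct

    rng = np.random.default_rng(seed)
    order = list(proteins)
    rng.shuffle(order)

    n_test_target = max(1, round(test_fraction * len(proteins)))
    train: list[str] = [order[0]]
    test: list[str] = []
    dropped: list[str] = []
    for p in order[1:]:
        i = idx[p]
        can_test = all(pid[i, idx[t]] < threshold_pct for t in train)
        can_train = all(pid[i, idx[t]] < threshold_pct for t in test)
        if len(test) < n_test_target and can_test:
            test.append(p)
        elif can_train:
            train.append(p)
        elif can_test:
            test.append(p)
        else:
            dropped.append(p)

    split = SplitSpec(
        train_proteins=train,
        test_proteins=test,
        dropped_proteins=dropped,
        identity_threshold_pct=float(threshold_pct),
        replicate_index=replicate_index,
        seed=int(seed),
    )
    if not split.test_proteins or not split.train_proteins:
        raise InfeasibleSplitError(
            "identity constraint admits no nonempty test set for this dataset"
        )
    assert verify_split(split, matrix), "internal error: emitted split fails verification"
    return split


def monte_carlo_splits(
    dataset,
    n_replicates: int = 5,
    threshold_pct: float = 20.0,
    seed: int = 0,
    test_fraction: float = 0.1,
    alignment_config: AlignmentConfig | None = None,
    matrix: IdentityMatrix | None = None,
) -> list[SplitSpec]:
    """``n_replicates`` independent splits; deterministic under ``seed``.

    The identity matrix is computed once and shared; replicate r uses the
    r-th child seed spawned from ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    proteins = _proteins_of(dataset)
    if matrix is None:
        matrix = identity_matrix(sorted(proteins), alignment_config)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    return [
        build_split(
            proteins,
            threshold_pct=threshold_pct,
            seed=int(child_seeds[r]),
            test_fraction=test_fraction,
            matrix=matrix,
            replicate_index=r + 1,
        )
        for r in range(n_replicates)
    ]
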