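"""Readers and writers for the package's file formats.

TSV interaction tables (BindingDB-style), curated-dataset TSV, FASTA
protein lists (via Biopython), one-SMILES-per-line .smi files, split
manifests (JSON) and score tables (TSV with ligand_id, group, score).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import CuratedDataset
from .scores import ScoreSet
from .splitting import SplitSpec

__all__ = [
    "read_interaction_table",
    "write_curated_dataset",
    "read_fasta",
    "write_fasta",
    "read_smi",
    "write_smi",
    "write_split",
    "read_split",
    "read_score_table",
    "write_score_table",
]


def read_interaction_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_curated_dataset(dataset: CuratedDataset, path) -> None:
    rows = [
        {
            "protein_id": r.protein_id,
            "protein_sequence": r.protein_sequence,
            "canonical_smiles": r.smiles,
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    SeqIO.write(records, str(path), "fasta")


def read_smi(path) -> list[str]:
    """One SMILES per line; an optional whitespace-separated id column is ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split()[0])
    return out


def write_smi(smiles_list, path, ids=None) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(smiles_list):
            fh.write(f"{s}\t{ids[i]}\n" if ids is not None else f"{s}\n")


def write_split(split: SplitSpec, path) -> None:
    Path(path).write_text(split.to_json())


def read_split(path) -> SplitSpec:
    return SplitSpec.from_json(Path(path).read_text())


def read_score_table(path) -> dict[str, ScoreSet]:
    """TSV with columns ligand_id, group, score -> label -> ScoreSet."""
    df = pd.read_csv(path, sep="\t")
    for col in ("group", "score"):
        if col not in df.columns:
            raise KeyError(f"score table missing column {col!r}")
    return {
        label: ScoreSet(label, np.asarray(sub["score"], dtype=float))
        for label, sub in df.groupby("group", sort=True)
    }


def write_score_table(sets: dict[str, ScoreSet], path) -> None:
    rows = []
    for label, ss in sets.items():
        for i, sc in enumerate(ss.scores):
            rows.append({"ligand_id": f"{label}_{i}", "group": label, "score": sc})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
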