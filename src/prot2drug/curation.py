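"""Curation of raw protein-ligand interaction tables.

Raw BindingDB-style rows are reduced to clean (protein, ligand) translation
pairs by seven selection criteria applied in order:

1. the curator organism field is one of the allowed source organisms
   (human, rat, mouse, cow by default);
2. the measured potency is below a cutoff (100 nM by default) with strict
   precedence IC50 -> Kd -> EC50: whichever measurement appears first in
   that order decides the row, even if a later one would pass;
3. the row carries a compound identifier (e.g. PubChem CID);
4. the row carries a SMILES string that the chemistry backend can parse;
5. molecular weight is strictly below 1000 Da;
6. the row carries a protein identifier (e.g. UniProt accession);
7. protein sequence length is strictly between 80 and 2050 residues.

Surviving SMILES are canonicalized with RDKit and duplicate
(protein sequence, canonical SMILES) pairs are dropped, keeping the first
occurrence.  Per-criterion drop counts are reported so a curation run can
be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

__all__ = [
    "InteractionRecord",
    "CuratedDataset",
    "FilterCriteria",
    "InvalidSmilesError",
    "MissingColumnError",
    "DEFAULT_COLUMNS",
    "canonicalize_smiles",
    "filter_records",
]

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: logical column name -> default column name in the input table
DEFAULT_COLUMNS = {
    "organism": "organism",
    "ic50_nM": "ic50_nM",
    "kd_nM": "kd_nM",
    "ec50_nM": "ec50_nM",
    "ligand_id": "ligand_id",
    "smiles": "smiles",
    "mol_weight_Da": "mol_weight_Da",
    "protein_id": "protein_id",
    "protein_sequence": "protein_sequence",
}

DEFAULT_ORGANISMS = ("Homo sapiens", "Rattus norvegicus", "Mus musculus", "Bos taurus")


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed/sanitized."""

    def __init__(self, smiles: str):
        super().__init__(f"invalid SMILES: {smiles!r}")
        self.smiles = smiles


class MissingColumnError(KeyError):
    """Raised when a mandatory column is absent from the input table."""


def canonicalize_smiles(smiles: str) -> str:
    """Return RDKit's canonical form of ``smiles``.

    Idempotent: canonicalizing a canonical string returns it unchanged.
    Raises :class:`InvalidSmilesError` for strings RDKit cannot sanitize.
    """
    if not isinstance(smiles, str) or not smiles:
        raise InvalidSmilesError(str(smiles))
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class InteractionRecord:
    """One curated protein-ligand interaction row (affinities in nM)."""

    protein_id: str
    protein_sequence: str
    ligand_id: str
    smiles: str
    organism: str = ""
    ic50_nM: float | None = None
    kd_nM: float | None = None
    ec50_nM: float | None = None
    mol_weight_Da: float = float("nan")


@dataclass
class CuratedDataset:
    """Filtered interaction records plus their unique proteins and ligands."""

    records: list[InteractionRecord]
    drop_counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0

    @property
    def unique_proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.protein_sequence)
        return list(seen)

    @property
    def unique_smiles(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.smiles)
        return list(seen)

    def pairs(self) -> list[tuple[str, str]]:
        return [(r.protein_sequence, r.smiles) for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FilterCriteria:
    """Thresholds of the record-selection rules; all inequalities strict."""

    organisms: tuple[str, ...] = DEFAULT_ORGANISMS
    affinity_max_nM: float = 100.0
    mol_weight_max_Da: float = 1000.0
    seq_len_min: int = 80
    seq_len_max: int = 2050
    deduplicate: bool = True


def _numeric(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Coerce to float; returns (values, unparsable-mask)."""
    present = series.notna() & (series.astype(str).str.strip() != "")
    values = pd.to_numeric(series, errors="coerce")
    unparsable = present & values.isna()
    return values, unparsable


def filter_records(
    raw_table: pd.DataFrame,
    criteria: FilterCriteria | None = None,
    columns: dict[str, str] | None = None,
) -> CuratedDataset:
    """Apply the seven selection criteria and canonicalize retained SMILES.

    ``columns`` maps the logical names of :data:`DEFAULT_COLUMNS` to actual
    column names in ``raw_table``.  Rows are evaluated independently, so the
    retained multiset does not depend on row order.  Rows with unparsable
    numeric fields are dropped with a logged reason.
    """
    criteria = criteria or FilterCriteria()
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    for logical, actual in colmap.items():
        if actual not in raw_table.columns:
            raise MissingColumnError(
                f"mandatory column {actual!r} (for {logical!r}) missing from input table"
            )

    df = raw_table.rename(columns={v: k for k, v in colmap.items()})
    n = len(df)

    ic50, bad_ic50 = _numeric(df["ic50_nM"])
    kd, bad_kd = _numeric(df["kd_nM"])
    ec50, bad_ec50 = _numeric(df["ec50_nM"])
    mw, bad_mw = _numeric(df["mol_weight_Da"])
    unparsable = bad_ic50 | bad_kd | bad_ec50 | bad_mw
    if unparsable.any():
        for idx in df.index[unparsable]:
            logger.warning("row %s dropped: unparsable numeric field", idx)

    def present(s: pd.Series) -> pd.Series:
        return s.notna() & (s.astype(str).str.strip() != "")

    ok_organism = df["organism"].astype(str).isin(criteria.organisms)
    # strict precedence IC50 -> Kd -> EC50
    cut = criteria.affinity_max_nM
    ok_affinity = pd.Series(
        np.where(
            ic50.notna(),
            ic50 < cut,
            np.where(kd.notna(), kd < cut, np.where(ec50.notna(), ec50 < cut, False)),
        ),
        index=df.index,
    )
    ok_ligand_id = present(df["ligand_id"])
    smiles_series = df["smiles"]
    has_smiles = present(smiles_series)
    canonical = pd.Series("", index=df.index, dtype=object)
    parses = has_smiles.copy()
    for idx in df.index[has_smiles]:
        try:
            canonical.at[idx] = canonicalize_smiles(str(smiles_series.at[idx]))
        except InvalidSmilesError:
            parses.at[idx] = False
            logger.warning("row %s dropped: unparsable SMILES", idx)
    ok_smiles = has_smiles & parses
    ok_mw = mw.notna() & (mw < criteria.mol_weight_max_Da)
    ok_protein_id = present(df["protein_id"])
    seq = df["protein_sequence"].astype(str)
    seq_len = seq.str.len()
    has_seq = present(df["protein_sequence"])
    ok_seq = has_seq & (seq_len > criteria.seq_len_min) & (seq_len < criteria.seq_len_max)

    stages = [
        ("unparsable_numeric", ~unparsable),
        ("organism", ok_organism),
        ("affinity", ok_affinity),
        ("ligand_id", ok_ligand_id),
        ("smiles", ok_smiles),
        ("mol_weight", ok_mw),
        ("protein_id", ok_protein_id),
        ("sequence_length", ok_seq),
    ]
    drop_counts: dict[str, int] = {}
    alive = pd.Series(True, index=df.index)
    for name, ok in stages:
        newly_dropped = int((alive & ~ok).sum())
        drop_counts[name] = newly_dropped
        alive &= ok

    records: list[InteractionRecord] = []
    seen_pairs: set[tuple[str, str]] = set()
    n_dupes = 0
    for idx in df.index[alive]:
        rec = InteractionRecord(
            protein_id=str(df.at[idx, "protein_id"]),
            protein_sequence=str(df.at[idx, "protein_sequence"]),
            ligand_id=str(df.at[idx, "ligand_id"]),
            smiles=canonical.at[idx],
            organism=str(df.at[idx, "organism"]),
            ic50_nM=None if pd.isna(ic50.at[idx]) else float(ic50.at[idx]),
            kd_nM=None if pd.isna(kd.at[idx]) else float(kd.at[idx]),
            ec50_nM=None if pd.isna(ec50.at[idx]) else float(ec50.at[idx]),
            mol_weight_Da=float(mw.at[idx]),
        )
        key = (rec.protein_sequence, rec.smiles)
        if criteria.deduplicate:
            if key in seen_pairs:
                n_dupes += 1
                continue
            seen_pairs.add(key)
        records.append(rec)
    drop_counts["duplicate_pair"] = n_dupes
    drop_counts["retained"] = len(records)
    return CuratedDataset(records=records, drop_counts=drop_counts, n_input=n)
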