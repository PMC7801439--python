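"""Molecule-level evaluation of generated SMILES.

Covers the standard de novo generation battery: chemical validity,
uniqueness, presence in a local reference database, physicochemical
property profiles (logP, MW, H-bond donors/acceptors, rotatable bonds,
TPSA, QED, SAS), compliance with drug-likeness rules (Lipinski-style
cutoffs plus TPSA and synthetic accessibility), and structural novelty as
nearest-neighbor Tanimoto similarity against a reference set.

Denominator conventions (each report records its own): validity is over
all generated strings; uniqueness over the valid canonical strings;
reference match over the unique valid canonical strings.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs, RDConfig, RDLogger
from rdkit.Chem import Crippen, Descriptors, QED, rdMolDescriptors

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit's contributed Ertl-Schuffenhauer SA score)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "EvaluationReport",
    "NoveltySummary",
    "FingerprintConfig",
    "DEFAULT_RULES",
    "validity_rate",
    "uniqueness_rate",
    "reference_match_rate",
    "property_profile",
    "compliance_table",
    "nearest_neighbor_tanimoto",
    "plot_property_histograms",
    "evaluate_generated",
]

#: drug-likeness rules: name -> (profile column, strict upper bound)
DEFAULT_RULES = {
    "logP < 5": ("logp", 5.0),
    "Molecular weight (Da) < 500": ("mol_weight_Da", 500.0),
    "Number of hydrogen donors < 5": ("n_h_donors", 5.0),
    "Number of hydrogen acceptors < 10": ("n_h_acceptors", 10.0),
    "Number of rotatable bonds < 10": ("n_rotatable_bonds", 10.0),
    "Topological polar surface area (A^2) < 140": ("tpsa_A2", 140.0),
    "Synthetic accessibility score < 6": ("sas", 6.0),
}

#: optional blood-brain-barrier rule
TPSA_BBB_RULE = {"Topological polar surface area (A^2) < 90": ("tpsa_A2", 90.0)}


@dataclass
class EvaluationReport:
    """Validity / uniqueness / reference-match percentages with denominators."""

    n_generated: int
    n_valid: int
    n_unique: int
    n_matched: int
    pct_valid: float
    pct_unique: float
    pct_reference_match: float

    def as_dict(self) -> dict:
        return {
            "n_generated": self.n_generated,
            "n_valid": self.n_valid,
            "n_unique": self.n_unique,
            "n_matched": self.n_matched,
            "pct_valid": self.pct_valid,
            "pct_unique": self.pct_unique,
            "pct_reference_match": self.pct_reference_match,
        }


@dataclass
class NoveltySummary:
    """Nearest-neighbor Tanimoto similarities of generated vs reference molecules."""

    nn_tanimoto: np.ndarray
    mean: float
    sd: float
    pct_above_085: float
    pct_below_05: float


@dataclass
class FingerprintConfig:
    """Fingerprint used for Tanimoto similarity (RDKit topological by default)."""

    kind: str = "rdkit"  # "rdkit" (topological path) or "morgan"
    n_bits: int = 2048
    morgan_radius: int = 2


def _mol(smiles: str):
    return Chem.MolFromSmiles(smiles)


def validity_rate(smiles_list) -> tuple[float, list[str]]:
    """Percent of parseable/sanitizable SMILES + their canonical forms."""
    smiles_list = list(smiles_list)
    if not smiles_list:
        raise ValueError("empty SMILES list")
    valid: list[str] = []
    for s in smiles_list:
        mol = _mol(s) if isinstance(s, str) and s else None
        if mol is not None:
            valid.append(Chem.MolToSmiles(mol))
    return 100.0 * len(valid) / len(smiles_list), valid


def uniqueness_rate(valid_canonical_list) -> float:
    """Percent of distinct strings in an already-canonical list."""
    lst = list(valid_canonical_list)
    if not lst:
        raise ValueError("empty list")
    return 100.0 * len(set(lst)) / len(lst)


def reference_match_rate(generated_canonical, reference_smiles) -> float:
    """Percent of generated canonical SMILES found in the reference set.

    ``reference_smiles`` is an iterable of SMILES (canonicalized here with
    the same backend) or a path to a .smi file.
    """
    gen = list(generated_canonical)
    if not gen:
        raise ValueError("empty generated list")
    if isinstance(reference_smiles, (str, os.PathLike)):
        from .io import read_smi

        reference_smiles = read_smi(reference_smiles)
    ref = set()
    for s in reference_smiles:
        mol = _mol(s)
        if mol is not None:
            ref.add(Chem.MolToSmiles(mol))
    return 100.0 * sum(1 for s in gen if s in ref) / len(gen)


def property_profile(valid_canonical_list) -> pd.DataFrame:
    """Per-molecule physicochemical properties and drug-likeness scores.

    Returns a DataFrame with one row per molecule and columns smiles, logp,
    mol_weight_Da, n_h_donors, n_h_acceptors, n_rotatable_bonds, tpsa_A2,
    qed, sas and smiles_length.  Molecules the backend fails on are
    excluded (a warning is recorded on stderr via RDKit's logger).
    """
    rows = []
    for s in valid_canonical_list:
        mol = _mol(s)
        if mol is None:
            continue
        try:
            rows.append(
                {
                    "smiles": s,
                    "logp": Crippen.MolLogP(mol),
                    "mol_weight_Da": Descriptors.MolWt(mol),
                    "n_h_donors": rdMolDescriptors.CalcNumHBD(mol),
                    "n_h_acceptors": rdMolDescriptors.CalcNumHBA(mol),
                    "n_rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds(mol),
                    "tpsa_A2": rdMolDescriptors.CalcTPSA(mol),
                    "qed": QED.qed(mol),
                    "sas": sascorer.calculateScore(mol),
                    "smiles_length": len(s),
                }
            )
        except Exception:  # pragma: no cover - backend failure on exotic input
            continue
    return pd.DataFrame(
        rows,
        columns=[
            "smiles",
            "logp",
            "mol_weight_Da",
            "n_h_donors",
            "n_h_acceptors",
            "n_rotatable_bonds",
            "tpsa_A2",
            "qed",
            "sas",
            "smiles_length",
        ],
    )


def compliance_table(profile: pd.DataFrame, rules: dict | None = None) -> dict:
    """Percent of molecules satisfying each drug-likeness rule + QED mean/sd.

    ``rules`` maps a rule name to (profile column, strict upper bound);
    unknown columns raise a configuration error.
    """
    if len(profile) == 0:
        raise ValueError("empty property profile")
    rules = rules or DEFAULT_RULES
    out: dict[str, float] = {}
    for name, (col, bound) in rules.items():
        if col not in profile.columns:
            raise KeyError(f"unknown profile column {col!r} in rule {name!r}")
        out[name] = 100.0 * float((profile[col] < bound).mean())
    out["QED mean"] = float(profile["qed"].mean())
    out["QED sd"] = float(profile["qed"].std(ddof=0))
    return out


def _fingerprint(mol, config: FingerprintConfig):
    if config.kind == "rdkit":
        return Chem.RDKFingerprint(mol, fpSize=config.n_bits)
    if config.kind == "morgan":
        return rdMolDescriptors.GetMorganFingerprintAsBitVect(
            mol, config.morgan_radius, nBits=config.n_bits
        )
    raise ValueError(f"unknown fingerprint kind {config.kind!r}")


def nearest_neighbor_tanimoto(
    generated, reference, config: FingerprintConfig | None = None
) -> NoveltySummary:
    """Max Tanimoto similarity of each generated molecule to the reference set."""
    config = config or FingerprintConfig()
    ref_fps = []
    for s in reference:
        mol = _mol(s)
        if mol is not None:
            ref_fps.append(_fingerprint(mol, config))
    if not ref_fps:
        raise ValueError("empty or unparsable reference set")
    sims = []
    for s in generated:
        mol = _mol(s)
        if mol is None:
            continue
        fp = _fingerprint(mol, config)
        sims.append(max(DataStructs.BulkTanimotoSimilarity(fp, ref_fps)))
    nn = np.asarray(sims, dtype=np.float64)
    if nn.size == 0:
        raise ValueError("no valid generated molecules to compare")
    return NoveltySummary(
        nn_tanimoto=nn,
        mean=float(nn.mean()),
        sd=float(nn.std(ddof=0)),
        pct_above_085=100.0 * float((nn > 0.85).mean()),
        pct_below_05=100.0 * float((nn < 0.5).mean()),
    )


def plot_property_histograms(profiles: dict, path) -> None:
    """Histogram grid of the numeric property columns, one panel each.

    ``profiles`` maps a dataset label (e.g. "generated", "training") to a
    property DataFrame; distributions are overlaid per panel the way
    generated-vs-training property comparisons are usually shown.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    columns = [
        ("logp", "logP"),
        ("n_h_donors", "H-bond donors"),
        ("n_h_acceptors", "H-bond acceptors"),
        ("n_rotatable_bonds", "rotatable bonds"),
        ("qed", "QED"),
        ("sas", "SAS"),
        ("tpsa_A2", "TPSA (A^2)"),
        ("mol_weight_Da", "molecular weight (Da)"),
        ("smiles_length", "SMILES length"),
    ]
    fig, axes = plt.subplots(3, 3, figsize=(11, 9))
    for ax, (col, label) in zip(axes.ravel(), columns):
        for name, profile in profiles.items():
            ax.hist(profile[col], bins=20, alpha=0.5, label=name, density=True)
        ax.set_xlabel(label)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def evaluate_generated(generated_smiles, reference_smiles=None) -> EvaluationReport:
    """Validity -> uniqueness -> reference-match pipeline with the
    package's denominator conventions."""
    generated_smiles = list(generated_smiles)
    pct_valid, valid = validity_rate(generated_smiles)
    unique = sorted(set(valid))
    pct_unique = uniqueness_rate(valid) if valid else 0.0
    if reference_smiles is not None and unique:
        pct_match = reference_match_rate(unique, reference_smiles)
        n_matched = round(pct_match * len(unique) / 100.0)
    else:
        pct_match, n_matched = 0.0, 0
    return EvaluationReport(
        n_generated=len(generated_smiles),
        n_valid=len(valid),
        n_unique=len(unique),
        n_matched=n_matched,
        pct_valid=pct_valid,
        pct_unique=pct_unique,
        pct_reference_match=pct_match,
    )
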