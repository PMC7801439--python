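"""Synthetic data generators: every pipeline stage testable without downloads.

Four generators:

* a *toy grammar* of paired (protein, SMILES) data in which planted
  amino-acid motifs map injectively to SMILES fragments — the target is the
  concatenation of the fragments of the motifs present, in order of
  occurrence.  The mapping is exactly learnable (a motif lookup reproduces
  every target), and all producible targets are chemically valid because
  the fragments are chosen to concatenate at single-bond-accepting atoms;
* toy BindingDB-style interaction tables whose rows exercise every branch
  of the record-selection criteria, with the expected retained count
  recorded in a manifest;
* two-group (and four-group) Normal score samples with known separation:
  under the lower-score-is-binder orientation the population AUC is
  Phi((mu_nonbinder - mu_binder) / (sigma * sqrt(2)));
* small named fixture molecule sets (.smi) with manifest metric values
  fixed by construction.

All generators are bit-reproducible under fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.stats import norm

from .scores import ScoreSet

__all__ = [
    "ToyGrammar",
    "SimulatedScoreConfig",
    "default_grammar",
    "make_toy_pairs",
    "make_toy_bindingdb_table",
    "make_random_proteins",
    "make_score_sets",
    "make_fixture_molecules",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_MOTIFS = ("MKW", "HQD", "CFN", "PYV", "RGT", "LSE", "AIW", "NDH")
_DEFAULT_FRAGMENTS = (
    "CCO",
    "c1ccccc1",
    "CC(C)N",
    "C1CCCCC1",
    "CCN",
    "c1ccncc1",
    "CC(=O)N",
    "COC",
)


@dataclass
class ToyGrammar:
    """Injective motif -> SMILES-fragment mapping with a concatenation linker."""

    motifs: tuple = _DEFAULT_MOTIFS
    fragments: tuple = _DEFAULT_FRAGMENTS
    seed: int = 0

    def __post_init__(self):
        if len(self.motifs) != len(self.fragments):
            raise ValueError("motifs and fragments must pair up one-to-one")
        if len(set(self.motifs)) != len(self.motifs) or len(set(self.fragments)) != len(
            self.fragments
        ):
            raise ValueError("motif -> fragment map must be injective")
        for f in self.fragments:
            if Chem.MolFromSmiles(f) is None:
                raise ValueError(f"fragment {f!r} is not a valid SMILES")

    @property
    def mapping(self) -> dict:
        return dict(zip(self.motifs, self.fragments))

    def target_for(self, protein: str) -> str:
        """The rule-generated SMILES: fragments of planted motifs in order."""
        hits = []
        for motif, frag in self.mapping.items():
            start = 0
            while True:
                i = protein.find(motif, start)
                if i < 0:
                    break
                hits.append((i, frag))
                start = i + 1
        hits.sort()
        return "".join(frag for _, frag in hits)


def default_grammar(seed: int = 0) -> ToyGrammar:
    return ToyGrammar(seed=seed)


def _motif_occurrences(protein: str, motifs) -> list[tuple[int, str]]:
    occ = []
    for m in motifs:
        start = 0
        while True:
            i = protein.find(m, start)
            if i < 0:
                break
            occ.append((i, m))
            start = i + 1
    return sorted(occ)


def make_toy_pairs(
    grammar: ToyGrammar,
    n_pairs: int = 2000,
    protein_len: int = 40,
    seed: int = 0,
    max_motifs: int = 3,
) -> list[tuple[str, str]]:
    """Random proteins with 1..max_motifs planted motifs and their rule targets.

    Each protein is a uniform random residue string with k (1..3) distinct
    motifs planted at non-overlapping positions; candidates with accidental
    extra motif occurrences are rejected and regenerated, so the planted
    occurrences are exactly the occurrences.  The paired SMILES is the
    concatenation of the planted motifs' fragments in order of position.
    """
    mlen = max(len(m) for m in grammar.motifs)
    if protein_len < mlen:
        raise ValueError("protein_len shorter than the longest motif")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    aa = np.array(list(AMINO_ACIDS))
    while len(pairs) < n_pairs:
        k = int(rng.integers(1, max_motifs + 1))
        chosen = rng.choice(len(grammar.motifs), size=k, replace=False)
        background = rng.choice(aa, size=protein_len)
        # place motifs at non-overlapping starts
        positions: list[int] = []
        ok = True
        for _ in range(k):
            for _attempt in range(50):
                p = int(rng.integers(0, protein_len - mlen + 1))
                if all(abs(p - q) >= mlen for q in positions):
                    positions.append(p)
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        prot = background.copy()
        for p, mi in zip(positions, chosen):
            prot[p : p + len(grammar.motifs[mi])] = list(grammar.motifs[mi])
        protein = "".join(prot)
        planted = sorted(
            (p, grammar.motifs[mi]) for p, mi in zip(positions, chosen)
        )
        if _motif_occurrences(protein, grammar.motifs) != planted:
            continue  # accidental motif in the background: regenerate
        target = "".join(grammar.mapping[m] for _, m in planted)
        pairs.append((protein, target))
    return pairs


def make_toy_bindingdb_table(seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """A raw interaction table exercising every selection-criterion branch.

    Returns (table, manifest); the manifest records which ligand ids must
    survive curation and the expected retained count.
    """
    rng = np.random.default_rng(seed)

    def seq(n: int) -> str:
        return "".join(np.random.default_rng(rng.integers(2**31)).choice(list(AMINO_ACIDS), size=n))

    good_seq = seq(120)
    rows = [
        # retained: IC50 passing
        dict(ligand_id="L1", organism="Homo sapiens", ic50_nM=10.0, kd_nM=None, ec50_nM=None,
             smiles="CCO", mol_weight_Da=46.07, protein_id="P1", protein_sequence=good_seq),
        # retained: IC50 missing, Kd passing
        dict(ligand_id="L2", organism="Rattus norvegicus", ic50_nM=None, kd_nM=50.0, ec50_nM=None,
             smiles="c1ccccc1", mol_weight_Da=78.11, protein_id="P2", protein_sequence=seq(150)),
        # retained: only EC50, passing
        dict(ligand_id="L3", organism="Mus musculus", ic50_nM=None, kd_nM=None, ec50_nM=99.9,
             smiles="CC(=O)Oc1ccccc1C(=O)O", mol_weight_Da=180.16, protein_id="P3",
             protein_sequence=seq(200)),
        # retained: boundary-passing lengths/MW
        dict(ligand_id="L4", organism="Bos taurus", ic50_nM=99.0, kd_nM=None, ec50_nM=None,
             smiles="CCN", mol_weight_Da=999.9, protein_id="P4", protein_sequence=seq(81)),
        # dropped: wrong organism
        dict(ligand_id="L5", organism="Danio rerio", ic50_nM=10.0, kd_nM=None, ec50_nM=None,
             smiles="CCO", mol_weight_Da=46.07, protein_id="P5", protein_sequence=seq(120)),
        # dropped: IC50 present and failing (Kd would pass, precedence is strict)
        dict(ligand_id="L6", organism="Homo sapiens", ic50_nM=100.0, kd_nM=1.0, ec50_nM=None,
             smiles="CCO", mol_weight_Da=46.07, protein_id="P6", protein_sequence=seq(120)),
        # dropped: all affinities missing
        dict(ligand_id="L7", organism="Homo sapiens", ic50_nM=None, kd_nM=None, ec50_nM=None,
             smiles="CCO", mol_weight_Da=46.07, protein_id="P7", protein_sequence=seq(120)),
        # dropped: no ligand identifier
        dict(ligand_id="", organism="Homo sapiens", ic50_nM=10.0, kd_nM=None, ec50_nM=None,
             smiles="CCO", mol_weight_Da=46.07, protein_id="P8", protein_sequence=seq(120)),
        # dropped: unparsable SMILES (unclosed ring)
        dict(ligand_id="L9", organism="Homo sapiens", ic50_nM=10.0, kd_nM=None, ec50_nM=None,
             smiles="C1CC", mol_weight_Da=100.0, protein_id="P9", protein_sequence=seq(120)),
        # dropped: MW exactly at the 1000 Da boundary (strict <)
        dict(ligand_id="L10", organism="Homo sapiens", ic50_nM=10.0, kd_nM=None, ec50_nM=None,
             smiles="CCO", mol_weight_Da=1000.0, protein_id="P10", protein_sequence=seq(120)),
        # dropped: no protein identifier
        dict(ligand_id="L11", organism="Homo sapiens", ic50_nM=10.0, kd_nM=None, ec50_nM=None,
             smiles="CCO", mol_weight_Da=46.07, protein_id="", protein_sequence=seq(120)),
        # dropped: sequence length exactly 80 (strict >)
        dict(ligand_id="L12", organism="Homo sapiens", ic50_nM=10.0, kd_nM=None, ec50_nM=None,
             smiles="CCO", mol_weight_Da=46.07, protein_id="P12", protein_sequence=seq(80)),
        # dropped: sequence length exactly 2050 (strict <)
        dict(ligand_id="L13", organism="Homo sapiens", ic50_nM=10.0, kd_nM=None, ec50_nM=None,
             smiles="CCO", mol_weight_Da=46.07, protein_id="P13", protein_sequence=seq(2050)),
        # dropped: duplicate of L1 on (protein sequence, canonical SMILES)
        dict(ligand_id="L14", organism="Homo sapiens", ic50_nM=20.0, kd_nM=None, ec50_nM=None,
             smiles="OCC", mol_weight_Da=46.07, protein_id="P1", protein_sequence=good_seq),
    ]
    table = pd.DataFrame(rows)
    manifest = {
        "expected_retained": 4,
        "expected_ligand_ids": ["L1", "L2", "L3", "L4"],
    }
    return table, manifest


def make_random_proteins(
    n: int = 30,
    length: int = 200,
    seed: int = 0,
    max_identity_pct: float | None = 15.0,
) -> list[str]:
    """Mutually dissimilar random protein sequences for splitting tests.

    Uniform random residue strings; when ``max_identity_pct`` is set, any
    candidate sharing at least that global-alignment identity with an
    already accepted sequence is rejected and redrawn, so the returned set
    is mutually below the cap.  Deterministic under ``seed``.
    """
    from .alignment import pairwise_identity

    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n:
            raise RuntimeError("could not generate a mutually dissimilar protein set")
        cand = "".join(rng.choice(aa, size=length))
        if max_identity_pct is not None and any(
            pairwise_identity(cand, s) >= max_identity_pct for s in out
        ):
            continue
        out.append(cand)
    return out


@dataclass
class SimulatedScoreConfig:
    """Normal score groups with a known effect size.

    Under the lower-is-binder orientation the closed-form population AUC of
    binders vs nonbinders is Phi((mu_nonbinder - mu_binder)/(sigma*sqrt(2))).
    """

    mu_binder: float = -9.0
    mu_nonbinder: float = -7.0
    sigma: float = 1.0
    n_per_group: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_per_group < 2:
            raise ValueError("need at least two scores per group")

    @property
    def closed_form_auc(self) -> float:
        return float(norm.cdf((self.mu_nonbinder - self.mu_binder) / (self.sigma * np.sqrt(2.0))))


def make_score_sets(config: SimulatedScoreConfig) -> tuple[dict, dict]:
    """Four labeled Normal score sets + manifest with the closed-form AUC.

    known_binders and generated_for_target draw from the binder
    distribution; random and generated_for_others from the nonbinder one.
    """
    rng = np.random.default_rng(config.seed)
    n, s = config.n_per_group, config.sigma
    sets = {
        "known_binders": ScoreSet("known_binders", rng.normal(config.mu_binder, s, n)),
        "random": ScoreSet("random", rng.normal(config.mu_nonbinder, s, n)),
        "generated_for_target": ScoreSet(
            "generated_for_target", rng.normal(config.mu_binder, s, n)
        ),
        "generated_for_others": ScoreSet(
            "generated_for_others", rng.normal(config.mu_nonbinder, s, n)
        ),
    }
    manifest = {
        "closed_form_auc_binders_vs_random": config.closed_form_auc,
        "n_per_group": n,
    }
    return sets, manifest


def make_fixture_molecules() -> tuple[dict, dict]:
    """Named SMILES fixture sets with by-construction expected metrics.

    Sets: ``all_valid`` (100% validity), ``all_invalid`` (0%),
    ``half_duplicated`` (50% uniqueness), and ``logp_rule`` — ten molecules
    of which exactly three (hexadecane, cholesterol, DDT) have
    Crippen logP >= 5, so the logP < 5 rule passes at 70%.
    """
    all_valid = ["CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "CCN", "COC", "C1CCCCC1"]
    all_invalid = ["xx", "((", "C1CC", "c1ccccc", "not_a_smiles", "))(("]
    half_duplicated = ["CCO", "CCO", "c1ccccc1", "c1ccccc1"]
    logp_rule = [
        "CC(=O)Oc1ccccc1C(=O)O",        # aspirin
        "CCO",                           # ethanol
        "c1ccccc1",                      # benzene
        "Cc1ccccc1",                     # toluene
        "Cn1cnc2c1c(=O)n(C)c(=O)n2C",    # caffeine
        "CC(C)Cc1ccc(cc1)C(C)C(=O)O",    # ibuprofen
        "CC(=O)Nc1ccc(O)cc1",            # paracetamol
        "CCCCCCCCCCCCCCCC",              # hexadecane, logP >= 5
        "CC(C)CCCC(C)C1CCC2C1(CCC3C2CC=C4C3(CCC(C4)O)C)C",  # cholesterol, logP >= 5
        "c1cc(ccc1C(c2ccc(cc2)Cl)C(Cl)(Cl)Cl)Cl",           # DDT, logP >= 5
    ]
    sets = {
        "all_valid": all_valid,
        "all_invalid": all_invalid,
        "half_duplicated": half_duplicated,
        "logp_rule": logp_rule,
    }
    manifest = {
        "all_valid": {"pct_valid": 100.0},
        "all_invalid": {"pct_valid": 0.0},
        "half_duplicated": {"pct_unique": 50.0},
        "logp_rule": {"pct_logp_lt_5": 70.0, "n": 10},
    }
    return sets, manifest
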