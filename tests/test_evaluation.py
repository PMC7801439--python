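"""Molecule metrics: validity/uniqueness/match, properties, compliance, novelty."""

import numpy as np
import pytest
from rdkit import Chem

from prot2drug.evaluation import (
    DEFAULT_RULES,
    FingerprintConfig,
    compliance_table,
    evaluate_generated,
    nearest_neighbor_tanimoto,
    property_profile,
    reference_match_rate,
    uniqueness_rate,
    validity_rate,
)
from prot2drug.synthetic import make_fixture_molecules


@pytest.fixture(scope="module")
def fixtures():
    return make_fixture_molecules()


def test_validity_mixed_list():
    pct, valid = validity_rate(["CCO", "C1CC", "c1ccccc1"])
    assert pct == pytest.approx(100 * 2 / 3, abs=1e-9)
    assert valid == ["CCO", "c1ccccc1"]


def test_validity_fixture_sets(fixtures):
    sets, manifest = fixtures
    pct_valid, _ = validity_rate(sets["all_valid"])
    assert pct_valid == manifest["all_valid"]["pct_valid"] == 100.0
    pct_invalid, none_valid = validity_rate(sets["all_invalid"])
    assert pct_invalid == manifest["all_invalid"]["pct_valid"] == 0.0
    assert none_valid == []


def test_validity_counts_conserved(fixtures):
    sets, _ = fixtures
    mixed = sets["all_valid"] + sets["all_invalid"]
    pct, valid = validity_rate(mixed)
    n_invalid = len(mixed) - len(valid)
    assert len(valid) + n_invalid == len(mixed)
    assert pct == pytest.approx(100.0 * len(valid) / len(mixed))


def test_validity_rejects_empty_input():
    with pytest.raises(ValueError):
        validity_rate([])


def test_uniqueness_canonical_duplicates(fixtures):
    sets, manifest = fixtures
    _, canon = validity_rate(sets["half_duplicated"])
    assert uniqueness_rate(canon) == manifest["half_duplicated"]["pct_unique"] == 50.0


def test_uniqueness_via_canonicalization_collapse():
    _, canon = validity_rate(["CCO", "OCC"])
    assert uniqueness_rate(canon) == 50.0


@pytest.mark.parametrize("n", [2, 4, 10])
def test_uniqueness_of_n_copies(n):
    assert uniqueness_rate(["CCO"] * n) == pytest.approx(100.0 / n)


def test_uniqueness_permutation_invariant(rng):
    lst = ["CCO", "CCN", "CCO", "c1ccccc1", "CCN"]
    shuffled = list(lst)
    rng.shuffle(shuffled)
    assert uniqueness_rate(lst) == uniqueness_rate(shuffled)


def test_reference_match_extremes_and_half(tmp_path):
    gen = ["CCO", "CCN", "COC", "c1ccccc1"]
    assert reference_match_rate(gen, gen) == 100.0
    assert reference_match_rate(gen, ["CCCC", "CCCCC"]) == 0.0
    assert reference_match_rate(gen, ["OCC", "NCC"]) == 50.0  # canonicalized overlap
    ref = tmp_path / "ref.smi"
    ref.write_text("OCC\nNCC\n")
    assert reference_match_rate(gen, ref) == 50.0


def test_property_profile_pinned_backend_values():
    profile = property_profile(["CC(=O)Oc1ccccc1C(=O)O", "CCO"])
    aspirin = profile.iloc[0]
    assert aspirin["mol_weight_Da"] == pytest.approx(180.16, abs=0.01)
    assert aspirin["n_h_donors"] == 1
    ethanol = profile.iloc[1]
    assert ethanol["n_h_donors"] == 1
    assert ethanol["n_h_acceptors"] == 1
    assert ethanol["n_rotatable_bonds"] == 0


def test_qed_in_unit_interval_random_fixture(fixtures):
    sets, _ = fixtures
    profile = property_profile(sets["all_valid"] + sets["logp_rule"])
    assert ((profile["qed"] >= 0) & (profile["qed"] <= 1)).all()
    assert (profile["tpsa_A2"] >= 0).all()
    assert (profile["sas"] >= 1).all()


def test_compliance_logp_rule_fixture(fixtures):
    """Ten molecules, exactly three with logP >= 5 -> 70% pass the logP rule."""
    sets, manifest = fixtures
    profile = property_profile(sets["logp_rule"])
    table = compliance_table(profile)
    assert table["logP < 5"] == manifest["logp_rule"]["pct_logp_lt_5"] == 70.0


def test_compliance_all_aspirin_satisfies_every_rule():
    profile = property_profile(["CC(=O)Oc1ccccc1C(=O)O"] * 3)
    table = compliance_table(profile)
    for rule in DEFAULT_RULES:
        assert table[rule] == 100.0
    assert 0.0 <= table["QED mean"] <= 1.0
    assert table["QED sd"] == 0.0


def test_compliance_thresholds_standard_values():
    """The rule set encodes the standard drug-likeness cutoffs exactly."""
    bounds = {col: bound for col, bound in DEFAULT_RULES.values()}
    assert bounds == {
        "logp": 5.0,
        "mol_weight_Da": 500.0,
        "n_h_donors": 5.0,
        "n_h_acceptors": 10.0,
        "n_rotatable_bonds": 10.0,
        "tpsa_A2": 140.0,
        "sas": 6.0,
    }


def test_compliance_unknown_rule_rejected():
    profile = property_profile(["CCO"])
    with pytest.raises(KeyError):
        compliance_table(profile, {"bogus rule": ("no_such_column", 1.0)})


def test_tanimoto_self_similarity_is_one(fixtures):
    sets, _ = fixtures
    novelty = nearest_neighbor_tanimoto(sets["all_valid"], sets["all_valid"])
    np.testing.assert_allclose(novelty.nn_tanimoto, 1.0)
    assert novelty.mean == 1.0
    assert novelty.pct_above_085 == 100.0


def test_tanimoto_benzene_toluene_matches_bitset_oracle():
    """|a & b| / |a | b| computed directly from the fingerprint bit sets."""
    for config in (FingerprintConfig("rdkit"), FingerprintConfig("morgan")):
        from prot2drug.evaluation import _fingerprint

        fa = _fingerprint(Chem.MolFromSmiles("c1ccccc1"), config)
        fb = _fingerprint(Chem.MolFromSmiles("Cc1ccccc1"), config)
        a, b = set(fa.GetOnBits()), set(fb.GetOnBits())
        expected = len(a & b) / len(a | b)
        novelty = nearest_neighbor_tanimoto(["c1ccccc1"], ["Cc1ccccc1"], config)
        assert novelty.nn_tanimoto[0] == pytest.approx(expected, abs=1e-12)


def test_tanimoto_symmetric_on_random_pairs(rng):
    from rdkit import DataStructs

    pool = ["CCO", "CCN", "c1ccccc1", "CC(=O)O", "C1CCCCC1", "c1ccncc1", "COC", "CC(C)C"]
    config = FingerprintConfig()
    from prot2drug.evaluation import _fingerprint

    for _ in range(50):
        a, b = rng.choice(pool, size=2, replace=False)
        fa = _fingerprint(Chem.MolFromSmiles(a), config)
        fb = _fingerprint(Chem.MolFromSmiles(b), config)
        assert DataStructs.TanimotoSimilarity(fa, fb) == pytest.approx(
            DataStructs.TanimotoSimilarity(fb, fa), abs=0
        )


def test_disjoint_fingerprints_score_zero():
    # an alkane and an aromatic ring share no path-fingerprint bits
    novelty = nearest_neighbor_tanimoto(["CCCC"], ["c1ccccc1"])
    assert novelty.nn_tanimoto[0] == 0.0


def test_empty_reference_rejected():
    with pytest.raises(ValueError):
        nearest_neighbor_tanimoto(["CCO"], [])


def test_evaluate_generated_denominators(fixtures):
    sets, _ = fixtures
    generated = sets["all_valid"] + sets["all_invalid"] + ["OCC"]  # dup of CCO
    report = evaluate_generated(generated, reference_smiles=sets["all_valid"])
    assert report.n_generated == 13
    assert report.n_valid == 7
    assert report.n_unique == 6
    assert report.pct_valid == pytest.approx(100 * 7 / 13)
    assert report.pct_unique == pytest.approx(100 * 6 / 7)
    assert report.pct_reference_match == 100.0


def test_compliance_agrees_with_independent_recomputation(fixtures):
    """An inline one-off recomputation straight from RDKit reproduces the
    compliance percentages."""
    from rdkit.Chem import Crippen, rdMolDescriptors

    sets, _ = fixtures
    smiles = sets["logp_rule"]
    profile = property_profile(smiles)
    table = compliance_table(profile)
    mols = [Chem.MolFromSmiles(s) for s in smiles]
    direct = {
        "logP < 5": 100.0 * sum(Crippen.MolLogP(m) < 5 for m in mols) / len(mols),
        "Number of hydrogen donors < 5": 100.0
        * sum(rdMolDescriptors.CalcNumHBD(m) < 5 for m in mols)
        / len(mols),
        "Topological polar surface area (A^2) < 140": 100.0
        * sum(rdMolDescriptors.CalcTPSA(m) < 140 for m in mols)
        / len(mols),
    }
    for rule, expected in direct.items():
        assert table[rule] == expected


def test_property_histograms_written(tmp_path, fixtures):
    from prot2drug.evaluation import plot_property_histograms

    sets, _ = fixtures
    profiles = {
        "generated": property_profile(sets["logp_rule"]),
        "training": property_profile(sets["all_valid"]),
    }
    out = tmp_path / "hist.png"
    plot_property_histograms(profiles, out)
    assert out.stat().st_size > 10_000  # a real multi-panel figure
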