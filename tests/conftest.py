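import numpy as np
import pytest

from prot2drug import synthetic
from prot2drug.tokenizer import build_vocabulary


@pytest.fixture(scope="session")
def grammar():
    return synthetic.default_grammar()


@pytest.fixture(scope="session")
def toy_pairs_small(grammar):
    """200 toy (protein, SMILES) pairs for fast unit tests."""
    return synthetic.make_toy_pairs(grammar, n_pairs=200, protein_len=40, seed=11)


@pytest.fixture(scope="session")
def toy_vocab(toy_pairs_small):
    return build_vocabulary([x for pair in toy_pairs_small for x in pair])


@pytest.fixture(scope="session")
def toy_table():
    return synthetic.make_toy_bindingdb_table(seed=5)


@pytest.fixture(scope="session")
def protein_set_30():
    """30 mutually <15%-identical random proteins (shared: costs ~400 alignments)."""
    return synthetic.make_random_proteins(n=30, length=200, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
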