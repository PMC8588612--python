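import numpy as np
import pytest

from paretogen import (GeneratorNet, build_vocabulary, make_corpus,
                       multi_target_objectives)


@pytest.fixture(scope="session")
def corpus():
    """Small synthetic corpus of valid SMILES (deterministic)."""
    return make_corpus(120, seed=7)


@pytest.fixture(scope="session")
def vocab(corpus):
    v, skipped = build_vocabulary(corpus)
    assert skipped == 0
    return v


@pytest.fixture(scope="session")
def objectives():
    """Two maximize + one minimize toy objectives."""
    return multi_target_objectives()


@pytest.fixture()
def tiny_generator(vocab):
    """Untrained miniature generator for fast mechanical tests."""
    return GeneratorNet(vocab, emb_dim=8, hidden_dim=12, n_layers=2,
                        max_len=40, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
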