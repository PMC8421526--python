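"""Shared fixtures: trained models at the documented default seeds.

Training is session-scoped so the full predictor stack is fitted once.
"""

import pytest

from cppscreen import (
    GeneratorSpec,
    generate_planted_protein,
    generate_training_set,
    train_composition_svm,
    train_skipgram_rf,
    train_zscale,
)


@pytest.fixture(scope="session")
def zscale_train_set():
    # 200 peptides total, the documented first-round training world
    return generate_training_set(GeneratorSpec(seed=1, n_cpp=100, n_noncpp=100))


@pytest.fixture(scope="session")
def zscale_model(zscale_train_set):
    return train_zscale(zscale_train_set)


@pytest.fixture(scope="session")
def train_set_seed7():
    return generate_training_set(GeneratorSpec(seed=7, n_cpp=200, n_noncpp=200))


@pytest.fixture(scope="session")
def test_set_seed8():
    return generate_training_set(GeneratorSpec(seed=8, n_cpp=100, n_noncpp=100))


@pytest.fixture(scope="session")
def svm_model(train_set_seed7):
    return train_composition_svm(train_set_seed7)


@pytest.fixture(scope="session")
def rf_model(train_set_seed7):
    return train_skipgram_rf(train_set_seed7, n_select=100, n_trees=200, seed=7)


@pytest.fixture(scope="session")
def planted_seed1():
    return generate_planted_protein(800, 2, seed=1)
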