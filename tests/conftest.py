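"""Shared fixtures: small synthetic datasets and quickly trained models.

Model-training fixtures use a reduced hyper-parameter grid so the unit
suite stays fast; the full grid protocol is exercised in the end-to-end
acceptance tests.
"""

import numpy as np
import pytest

from cppred import (GeneratorConfig, GridSpec, default_motifs, encode_dataset,
                    make_dataset)
from cppred.svm_model import train

SMALL_GRID = GridSpec(gamma=(1e-3, 1e-2, 1e-1), cost=(1.0, 5.0, 10.0),
                      weight=(1.0,))


@pytest.fixture(scope="session")
def small_dataset():
    d, _ = make_dataset(GeneratorConfig(n_pos=60, n_neg=60, seed=7))
    return d


@pytest.fixture(scope="session")
def planted_dataset():
    cfg = GeneratorConfig(n_pos=60, n_neg=60, seed=9,
                          plant_motif="RRRRRRR", plant_prob=0.5)
    d, _ = make_dataset(cfg)
    return d


@pytest.fixture(scope="session")
def motifs():
    return default_motifs()


@pytest.fixture(scope="session")
def comp_model(small_dataset):
    X, y = encode_dataset(small_dataset, "composition")
    return train(X.to_numpy(), y, grid=SMALL_GRID, k=3, seed=0,
                 scheme="composition")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
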