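import numpy as np
import pandas as pd
import pytest

import methylearn as ml
from methylearn import nn


@pytest.fixture(scope="session")
def tiny_study() -> ml.SyntheticStudy:
    """Small balanced study with planted effects in every class."""
    cfg = ml.SyntheticConfig(
        n_provenances=3,
        genotypes_per_provenance=2,
        n_cpg=1500,
        n_tissue_cpg=40,
        n_provenance_cpg=40,
        n_trait_cpg=40,
        seed=7,
    )
    return ml.simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study() -> ml.SyntheticStudy:
    """No planted effects: every CpG is null."""
    cfg = ml.SyntheticConfig(
        n_provenances=5,
        genotypes_per_provenance=1,
        n_cpg=2000,
        n_tissue_cpg=0,
        n_provenance_cpg=0,
        n_trait_cpg=0,
        missing_rate=0.0,
        seed=2,
    )
    return ml.simulate_study(cfg)


@pytest.fixture(scope="session")
def toy_classification():
    """Linearly separable two-class problem with a 2-sd margin."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-2, 1, size=(10, 2)), rng.normal(2, 1, size=(10, 2))])
    y = np.array([0] * 10 + [1] * 10)
    return X, y


@pytest.fixture(scope="session")
def fitted_small_classifier(toy_classification):
    X, y = toy_classification
    spec = nn.NetworkSpec(
        n_inputs=2, hidden_sizes=(8, 8), epochs=200, learning_rate=0.05, seed=0
    )
    model = nn.train_sgd(nn.init_network(spec), X, y)
    return model, X, y
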