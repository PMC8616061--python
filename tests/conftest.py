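import warnings

import numpy as np
import pytest

from emplex import (
    GeneSignature,
    SimConfig,
    build_consensus,
    generate_emt_dataset,
    preprocess,
    select_k,
    soft_cluster,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One default 4-state synthetic experiment, shared across tests."""
    return generate_emt_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_expression(default_dataset):
    filtered, expr = preprocess(default_dataset.counts)
    return filtered, expr


@pytest.fixture(scope="session")
def default_signatures(default_dataset):
    return (
        GeneSignature("epithelial", tuple(default_dataset.epithelial_genes)),
        GeneSignature("mesenchymal", tuple(default_dataset.mesenchymal_genes)),
    )


@pytest.fixture(scope="session")
def default_clustering(default_expression):
    """Consensus + soft memberships on the shared dataset."""
    _, expr = default_expression
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cons = build_consensus(expr, seed=11)
        k = select_k(cons)
        memb = soft_cluster(cons, k, seed=11)
    return cons, memb


@pytest.fixture
def rng():
    return np.random.default_rng(0)
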