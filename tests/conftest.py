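"""Shared fixtures: the full training build is expensive (~10 s), so the
supergraph, descriptor matrix and headline model are session-scoped."""

import numpy as np
import pytest

from repelqsar.atomic_fields import compute_fields
from repelqsar.dataset_io import load_training_set, log_activity
from repelqsar.molgraph import parse_smiles
from repelqsar.pls_qsar import factor_dynamics, fit_pls
from repelqsar.supergraph import build_msg, descriptor_matrix


@pytest.fixture(scope="session")
def training_records():
    return load_training_set()


@pytest.fixture(scope="session")
def training_graphs(training_records):
    return [parse_smiles(r.smiles, r.id) for r in training_records]


@pytest.fixture(scope="session")
def field_vectors(training_graphs):
    return {g.id: compute_fields(g) for g in training_graphs}


@pytest.fixture(scope="session")
def msg_and_mappings(training_graphs):
    return build_msg(training_graphs)


@pytest.fixture(scope="session")
def training_matrix(msg_and_mappings, field_vectors):
    sg, maps = msg_and_mappings
    X, mask = descriptor_matrix(sg, maps, field_vectors)
    return X, mask


@pytest.fixture(scope="session")
def training_activity(training_records):
    return log_activity(training_records, censoring="use-bound")


@pytest.fixture(scope="session")
def headline_model(training_matrix, training_activity):
    X, _ = training_matrix
    return fit_pls(X, training_activity, 6)


@pytest.fixture(scope="session")
def headline_dynamics(training_matrix, training_activity):
    X, _ = training_matrix
    return factor_dynamics(X, training_activity, k_max=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
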