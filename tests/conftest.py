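"""Shared fixtures: the default simulated benchmark dataset."""

from __future__ import annotations

import numpy as np
import pytest

from glycoshift.encoding import descriptor_matrix
from glycoshift.records import labels_frame
from glycoshift.simulate import default_increment_model, generate_dataset

DEFAULT_N = 273
DEFAULT_N_DI = 154
DEFAULT_N_TRI = 119
DEFAULT_NOISE = 0.3
DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_records():
    model = default_increment_model(noise_sd=DEFAULT_NOISE)
    dataset = generate_dataset(
        DEFAULT_N, {"n_di": DEFAULT_N_DI, "n_tri": DEFAULT_N_TRI}, model, seed=DEFAULT_SEED
    )
    return dataset.records


@pytest.fixture(scope="session")
def default_matrix(default_records):
    X, ids = descriptor_matrix(default_records)
    return X, ids


@pytest.fixture(scope="session")
def default_labels(default_records):
    return labels_frame(default_records).reset_index(drop=True)


def accuracy(y_pred, y_true) -> float:
    a = np.asarray(list(y_pred), dtype=object)
    b = np.asarray(list(y_true), dtype=object)
    return float(np.mean(a == b))
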