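"""Shared fixtures: the synthetic two-class library and small trained models.

Everything is generated programmatically with fixed seeds; training uses
reduced layer widths so the whole suite stays fast on one CPU.
"""

import numpy as np
import pytest

import adascreen as ada
from adascreen.neuralmodels import DNNConfig, NFPConfig, train_dnn, train_nfp

LIB_SEED = 11
SPLIT_SEED = 5
NBITS = 512


@pytest.fixture(scope="session")
def synthetic_library():
    """100 scaffold-family actives + 100 acyclic background molecules."""
    records, truth = ada.generate_synthetic_library(
        seed=LIB_SEED, n_positive_like=100, n_background=100)
    return records, truth


@pytest.fixture(scope="session")
def library_arrays(synthetic_library):
    """Fingerprint matrix, graphs, labels and a 70/30 split of the library."""
    records, _ = synthetic_library
    X = np.array([ada.ecfp4(r, NBITS).bits for r in records], dtype=float)
    graphs = [ada.mol_graph(r) for r in records]
    y = np.array([1 if r.label == "active" else 0 for r in records])
    split = ada.split_dataset(records, (7, 3, 0), seed=SPLIT_SEED)
    idx_train = [i for i, r in enumerate(records) if r.id in split.train]
    idx_test = [i for i, r in enumerate(records) if r.id in split.test]
    return {"records": records, "X": X, "graphs": graphs, "y": y,
            "idx_train": idx_train, "idx_test": idx_test}


@pytest.fixture(scope="session")
def trained_dnn(library_arrays):
    la = library_arrays
    config = DNNConfig(batch_size=32, num_epochs=40, hidden_widths=(64, 32),
                       seed=3)
    params, log = train_dnn(la["X"][la["idx_train"]],
                            la["y"][la["idx_train"]], config)
    return params, log


@pytest.fixture(scope="session")
def trained_nfp(library_arrays):
    la = library_arrays
    config = NFPConfig(conv_layers=2, fp_length=64, hidden_width=32,
                       batch_size=25, num_epochs=60, seed=3)
    graphs = [la["graphs"][i] for i in la["idx_train"]]
    params, log = train_nfp(graphs, la["y"][la["idx_train"]], config)
    return params, log
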