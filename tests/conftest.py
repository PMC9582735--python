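"""Shared fixtures: reference molecules, synthetic benchmarks, trained models.

The two benchmark fixtures (noiseless and noise sigma=0.1) are session-scoped:
they generate 400 synthetic molecules, enumerate and oracle-score all
modifications, split by molecule, and train a 3-layer graph convolution model
for 50 epochs — the standard desk-scale study conditions used throughout the
evaluation tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from deltadock.chem import parse_smiles
from deltadock.data import make_oracle_dataset, split_dataset
from deltadock.models import GNNNodeRegressor, MajoritySignBaseline

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benzene():
    return parse_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def pyridine():
    return parse_smiles("c1ccncc1", "pyridine")


@pytest.fixture(scope="session")
def fixture_set_100():
    from deltadock.data import generate_fixtures

    return generate_fixtures(100, seed=11)


def _benchmark(sigma: float):
    graphs, params = make_oracle_dataset(400, seed=1, sigma=sigma)
    spec = split_dataset(graphs, mode="random", test_fraction=0.2, n_folds=5, seed=1)
    by_id = {g.id: g for g in graphs}
    train = [by_id[i] for i in spec.folds]
    test = [by_id[i] for i in spec.test_ids]
    model = GNNNodeRegressor(
        n_conv=3, layer_type="gcn", hidden=256, epochs=50, batch_size=256,
        learning_rate=0.01, dropout=0.2, random_state=1,
    )
    model.fit(train, validation=test)
    return {"graphs": graphs, "params": params, "train": train, "test": test, "model": model}


@pytest.fixture(scope="session")
def noiseless_benchmark():
    """400 noiseless oracle fixtures + trained 3-layer GCN (sigma = 0)."""
    return _benchmark(0.0)


@pytest.fixture(scope="session")
def noisy_benchmark():
    """The default sigma=0.1 synthetic benchmark + trained 3-layer GCN."""
    return _benchmark(0.1)


@pytest.fixture(scope="session")
def small_model():
    """A small trained GCN on 40 noiseless fixtures, for gradient/saliency tests."""
    graphs, params = make_oracle_dataset(40, seed=3, sigma=0.0)
    model = GNNNodeRegressor(hidden=32, epochs=30, batch_size=32, random_state=3)
    model.fit(graphs[:32], validation=graphs[32:])
    return {"graphs": graphs, "params": params, "model": model}


def held_out_arrays(bench):
    """Stack held-out predictions, labels and masks of a benchmark fixture."""
    test = bench["test"]
    pred = np.vstack(bench["model"].predict(test))
    true = np.vstack([g.labels.values for g in test])
    mask = np.vstack([g.labels.mask for g in test])
    return pred, true, mask
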