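"""Shared fixtures: small synthetic datasets generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from clpbench.synthetic_data import (SyntheticConfig, generate_classification_set,
                                     generate_regression_set)


@pytest.fixture(scope="session")
def classification_records():
    """300 molecules, 10% actives, no label noise."""
    cfg = SyntheticConfig(task="classification", n_molecules=300, seed=11)
    return generate_classification_set(cfg)


@pytest.fixture(scope="session")
def classification_records_1k():
    """1000 molecules for split-scale tests."""
    cfg = SyntheticConfig(task="classification", n_molecules=1000, seed=13)
    return generate_classification_set(cfg)


@pytest.fixture(scope="session")
def regression_records():
    """400 molecules in analog series with planted linear signal."""
    cfg = SyntheticConfig(task="regression", n_molecules=400, noise_sd=0.3,
                          seed=17)
    return generate_regression_set(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
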