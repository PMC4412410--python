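"""Shared fixtures: synthetic experiments at the default study conditions."""

import numpy as np
import pytest

from motorpls import GeneratorConfig, generate_ensemble


@pytest.fixture(scope="session")
def default_cycles():
    """Ground-truth-aligned ensemble/signals pair at the default conditions."""
    ens, sig, truth = generate_ensemble(GeneratorConfig(), seed=0)
    return ens, sig, truth


@pytest.fixture(scope="session")
def small_cycles():
    """A small, fast experiment for structural tests."""
    cfg = GeneratorConfig(n_cycles=60, n_samples=100, sample_rate=2000.0)
    ens, sig, truth = generate_ensemble(cfg, seed=1)
    return ens, sig, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
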