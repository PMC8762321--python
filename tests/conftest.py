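"""Shared fixtures: the calibrated fixture configuration and, for the
closed-loop tests, one trained model reused across the whole session."""

from __future__ import annotations

import numpy as np
import pytest

from bgreach import calibrate, default_config, train_model


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def calibrated(cfg):
    """Configuration with the dopamine read-out and STN coupling map
    re-fitted from scratch (seeded)."""
    new_cfg, diag = calibrate(cfg, seed=0)
    return new_cfg, diag


@pytest.fixture(scope="session")
def maps(cfg):
    """Cortical maps trained once per test session (~30 s)."""
    return train_model(cfg, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
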