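"""Shared fixtures: small deterministic models and maps.

Session-scoped fixtures are read-only; tests must copy before mutating.
"""
import warnings

import numpy as np
import pytest

from emfit.synth import build_ideal_helix, simulate_map

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def helix20():
    return build_ideal_helix(20)


@pytest.fixture(scope="session")
def helix20_map(helix20):
    c = helix20.centroid()
    return simulate_map(helix20, (40, 40, 40), 1.0, 3.5, origin=c - 20.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
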