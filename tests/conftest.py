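"""Shared fixtures: a default transducer, its reflector reference, and a
fast phantom spec with a short standoff so RF traces stay small."""

import numpy as np
import pytest

from cartiqus.synthetic import CartilagePhantomSpec, TransducerSpec, simulate_reference


@pytest.fixture(scope="session")
def transducer() -> TransducerSpec:
    return TransducerSpec()


@pytest.fixture(scope="session")
def reference(transducer):
    return simulate_reference(transducer)


@pytest.fixture
def fast_phantom_spec() -> CartilagePhantomSpec:
    """Short-standoff phantom: same physics, ~4x shorter traces."""
    return CartilagePhantomSpec(standoff_mean_mm=3.0, n_lines=25, seed=11)


@pytest.fixture(scope="session")
def fast_reference(transducer):
    return simulate_reference(transducer, standoff_mm=3.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
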