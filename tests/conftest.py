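import numpy as np
import pytest

from syncore import CensusSettings, load_fixture


@pytest.fixture
def odd2cycle():
    return load_fixture("odd2cycle_w16")


@pytest.fixture
def chaotic_core():
    return load_fixture("chaotic_core")


@pytest.fixture
def pair_generative():
    return load_fixture("pair_generative")


@pytest.fixture
def pair_conservative():
    return load_fixture("pair_conservative")


@pytest.fixture
def fast_settings():
    """Census settings scaled down for unit tests of plumbing."""
    return CensusSettings(n_transient=2_000, n_record=400, lyap_steps=4_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
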