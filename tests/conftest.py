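import numpy as np
import pytest

from mrkit import published


@pytest.fixture(scope="session")
def isoleucine_pairs():
    """The four non-pleiotropic isoleucine instruments from the published lead-variant table."""
    return published.instrument_pairs("isoleucine")


@pytest.fixture(scope="session")
def lead_table():
    return published.bcaa_lead_variants()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_160_0)
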