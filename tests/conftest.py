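import pytest

import blueharvest as bh
from blueharvest.ecology import MassAxis


@pytest.fixture(scope="session")
def axis():
    return MassAxis.default()


@pytest.fixture(scope="session")
def params():
    return bh.default_parameters()


@pytest.fixture(scope="session")
def grid8():
    return bh.make_grid(8)


@pytest.fixture(scope="session")
def forcing8():
    """Noise-free 8-degree forcing over the historical window."""
    return bh.generate_synthetic_forcing(
        bh.ForcingSpec(resolution_deg=8, base_year=1950, end_year=2006,
                       noise_sd=0.0, seed=0)
    )
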