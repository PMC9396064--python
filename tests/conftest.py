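import pytest

from pnaokin import InstrumentModel, RateParameterSet, default_extinction_table

UM = 1e-6


@pytest.fixture
def params():
    return RateParameterSet()


@pytest.fixture
def table():
    return default_extinction_table()


@pytest.fixture
def quiet_instrument():
    """Noiseless instrument for oracle comparisons."""
    return InstrumentModel(noise_sd=0.0, seed=0)


@pytest.fixture
def noisy_instrument():
    return InstrumentModel(seed=7)
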