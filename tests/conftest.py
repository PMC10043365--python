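import numpy as np
import pytest

from nsclc_cea import (RunConfig, TABLE1_CURVES, baseline_values, load_table,
                       atezolizumab_strategy, chemotherapy_strategy)


@pytest.fixture(scope="session")
def table():
    return load_table()


@pytest.fixture()
def values(table):
    """Fresh baseline parameter values (mutable per test)."""
    return baseline_values(table)


@pytest.fixture(scope="session")
def curves():
    return TABLE1_CURVES


@pytest.fixture()
def config():
    return RunConfig()


@pytest.fixture()
def atezo_spec():
    return atezolizumab_strategy()


@pytest.fixture()
def chemo_spec():
    return chemotherapy_strategy()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230314)
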