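import warnings

import numpy as np
import pytest

from tightbind.fixtures import load_fixture
from tightbind.simulate import SimNoise


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Domain warnings (conditioning, exclusions) are asserted explicitly
    where they matter; elsewhere they are noise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def zero_noise():
    return SimNoise(0.0, 0.0, 0.0, 0)


@pytest.fixture(scope="session")
def fx_progress_25():
    return load_fixture("pernisine_25C")


@pytest.fixture(scope="session")
def fx_progress_50():
    return load_fixture("pernisine_50C")


@pytest.fixture(scope="session")
def fx_itc_25():
    return load_fixture("itc_25C")


@pytest.fixture(scope="session")
def fx_itc_50():
    return load_fixture("itc_50C")


@pytest.fixture(scope="session")
def fx_dsf_up():
    return load_fixture("dsf_UP")


@pytest.fixture(scope="session")
def fx_dsf_ap():
    return load_fixture("dsf_AP")
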