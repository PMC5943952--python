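import pytest

from atomgroups import LOG_ETA_293K, LOG_GAMMA_INF_298K, load_packaged
from atomgroups.synthetic import fixture_molecules


@pytest.fixture(scope="session")
def visc_table():
    return load_packaged(LOG_ETA_293K)


@pytest.fixture(scope="session")
def gamma_table():
    return load_packaged(LOG_GAMMA_INF_298K)


@pytest.fixture(scope="session")
def fixtures():
    return {f.name: f for f in fixture_molecules()}
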