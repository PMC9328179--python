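import pytest

from ptscan.signal_tables import default_pts2_spec, default_tables


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture(scope="session")
def relaxed_spec():
    return default_pts2_spec(mode="relaxed")


@pytest.fixture(scope="session")
def strict_spec():
    return default_pts2_spec(mode="strict")
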