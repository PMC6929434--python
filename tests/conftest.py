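import pytest

from biounits.fixtures import fixture_suite
from biounits.library import build_library, default_pbus, default_seed_units


@pytest.fixture(scope="session")
def suite():
    return fixture_suite()


@pytest.fixture(scope="session")
def suite_by_name(suite):
    return {f.name: f for f in suite}


@pytest.fixture(scope="session")
def default_lib():
    return build_library(default_seed_units(), default_pbus())
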