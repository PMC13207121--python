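import pytest

from adfunnel.filters import FilterConfig
from adfunnel.fixtures import family_worked_example, load_family_pedigree
from adfunnel.panels import default_panels


@pytest.fixture(scope="session")
def family_ped():
    return load_family_pedigree()


@pytest.fixture(scope="session")
def panels():
    return default_panels()


@pytest.fixture(scope="session")
def cfg():
    return FilterConfig()


@pytest.fixture(scope="session")
def worked_example():
    """The published three-variant family example plus seven distractors."""
    return family_worked_example()
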