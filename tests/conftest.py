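import importlib.resources

import pytest
from hypothesis import settings

from cub import SyntheticSpec, extract_all_cds, get_code, read_genbank

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code5():
    return get_code(5)


@pytest.fixture(scope="session")
def code1():
    return get_code(1)


@pytest.fixture(scope="session")
def fixture_path(tmp_path_factory):
    """Path to the packaged synthetic GenBank fixture."""
    with importlib.resources.as_file(
        importlib.resources.files("cub.data").joinpath("fixture.gb")
    ) as p:
        yield p


@pytest.fixture(scope="session")
def fixture_spec():
    """The generator settings the packaged fixture was emitted with."""
    return SyntheticSpec(seed=42)


@pytest.fixture(scope="session")
def fixture_genome(fixture_path):
    return read_genbank(fixture_path)


@pytest.fixture(scope="session")
def fixture_cds(fixture_genome, code5):
    return extract_all_cds(fixture_genome, code5)
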