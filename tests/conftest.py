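import pytest

from numtkit import annotate_assembly
from numtkit import synth_fixtures as sf


@pytest.fixture(scope="session")
def basic_fixture():
    return sf.preset_basic(seed=42)


@pytest.fixture(scope="session")
def basic_loci(basic_fixture):
    return annotate_assembly(basic_fixture.records, basic_fixture.mito)


@pytest.fixture(scope="session")
def dimorph_fixture():
    return sf.preset_dimorph(seed=42)


@pytest.fixture(scope="session")
def population_fixture():
    return sf.preset_population(seed=42)


@pytest.fixture(scope="session")
def outgroup_fixture():
    return sf.preset_outgroup(seed=42)


@pytest.fixture(scope="session")
def small_mito():
    return sf.make_mito(L=4000, seed=7)
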