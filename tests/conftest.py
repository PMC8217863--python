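import pytest

from plumhap.model import reference_catalog, reference_gene_map
from plumhap.simulate import SimulationConfig, rare_haplotype_definitions


@pytest.fixture(scope="session")
def catalog():
    """The published six-haplotype plum MYB10 catalog."""
    return reference_catalog()


@pytest.fixture(scope="session")
def gene_map():
    return reference_gene_map()


@pytest.fixture(scope="session")
def truth_band_sets(catalog):
    return {frozenset(h.bands) for h in catalog.haplotypes}


@pytest.fixture(scope="session")
def rare_haplotypes():
    return rare_haplotype_definitions()


@pytest.fixture
def config_factory():
    def make(**kwargs):
        return SimulationConfig(**kwargs)

    return make
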