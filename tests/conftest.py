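import pytest

from screenforge import make_slc_library, make_toy_annotation, make_toy_genome


@pytest.fixture(scope="session")
def toy_annotation():
    return make_toy_annotation(30, chrom_length=200_000, exon_fraction=0.4,
                               seed=7)


@pytest.fixture(scope="session")
def toy_genome(toy_annotation):
    return make_toy_genome(toy_annotation, seed=7)


@pytest.fixture(scope="session")
def slc_library():
    return make_slc_library(seed=0)
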