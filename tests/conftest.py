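import pytest

from stopin.fixtures import (
    aex2_like_spec,
    coverage_spec,
    load_fixture,
    make_edited_pair,
)


@pytest.fixture(scope="session")
def coverage_fixture():
    """Genome + gene models + manifest covering gene strand x PAM strand x
    insertion phase, plus a two-isoform gene."""
    genome, genes, manifest = load_fixture(coverage_spec())
    return genome, {g.gene_id: g for g in genes}, manifest


@pytest.fixture(scope="session")
def aex2_pair():
    """Matched wild-type/knock-in genomes for the aex-2-like locus."""
    return make_edited_pair(aex2_like_spec())


@pytest.fixture(scope="session")
def aex2_fixture():
    genome, genes, manifest = load_fixture(aex2_like_spec())
    return genome, genes[0], manifest
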