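import pytest

from deamipred.fixtures import (
    PeptideSpec,
    build_benchmark,
    build_peptide,
    build_structure,
    synthetic_half_life_table,
)
from deamipred.structure import enumerate_asn_sites, select_chain


@pytest.fixture(scope="session")
def half_life_table():
    return synthetic_half_life_table()


@pytest.fixture()
def ganga_spec():
    return PeptideSpec("GANGA", phi=-60.0, psi=-45.0, chi1=-65.0, chi2=-20.0)


@pytest.fixture()
def ganga_structure(ganga_spec):
    return build_structure(ganga_spec)


@pytest.fixture()
def ganga_pdb_text(ganga_spec):
    return build_peptide(ganga_spec)


@pytest.fixture()
def ganga_site(ganga_structure):
    chain = select_chain(ganga_structure)
    return chain, enumerate_asn_sites(chain)[0]


@pytest.fixture(scope="session")
def benchmark():
    return build_benchmark(seed=20170721)
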