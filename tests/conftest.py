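import pytest

from nat2typer import default_allele_table, default_reference, default_snp_catalog


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def catalog(reference):
    return default_snp_catalog(reference)


@pytest.fixture(scope="session")
def allele_table(reference):
    return default_allele_table(reference)
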