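import pytest

from slowcodon.orf import (
    default_rate_table,
    load_guides,
    load_orf,
    packaged_data,
)


@pytest.fixture(scope="session")
def egfp():
    return load_orf(packaged_data("egfp_cds.fasta"))


@pytest.fixture(scope="session")
def rate_table():
    return default_rate_table()


@pytest.fixture(scope="session")
def guides():
    return load_guides(packaged_data("sirna_guides_synthetic.fasta"))
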