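import pytest

from circamp import (
    backsplice_probes,
    five_prime_probes,
    synthetic_locus,
    three_prime_probes,
)


@pytest.fixture(scope="session")
def locus():
    return synthetic_locus()


@pytest.fixture(scope="session")
def five_probes(locus):
    return five_prime_probes(locus)


@pytest.fixture(scope="session")
def three_probes(locus):
    return three_prime_probes(locus)


@pytest.fixture(scope="session")
def circ_probes(locus):
    return backsplice_probes(locus)
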