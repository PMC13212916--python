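import pytest

from nucpack import synth


@pytest.fixture(scope="session")
def example_library():
    return synth.example_library()


@pytest.fixture(scope="session")
def duplex_b():
    """4-bp idealized B-form DNA duplex covering all four nucleotides."""
    return synth.toy_duplex("GACT", "B")


@pytest.fixture(scope="session")
def duplex_gcgc():
    return synth.toy_duplex("GCGC", "B")
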