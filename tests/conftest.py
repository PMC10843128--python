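import pytest

from infodecomp.fixtures import giant_bit, logic_gate, uniform


@pytest.fixture(scope="session")
def xor():
    return logic_gate("XOR")


@pytest.fixture(scope="session")
def uniform3():
    return uniform(3, 2)


@pytest.fixture(scope="session")
def giant3():
    return giant_bit(3)
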