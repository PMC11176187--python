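import numpy as np
import pytest

from booltaylor import BooleanNetwork, TruthTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def and2():
    return TruthTable(2, [0, 0, 0, 1], ("x1", "x2"))


@pytest.fixture
def xor2():
    return TruthTable(2, [0, 1, 1, 0], ("x1", "x2"))


@pytest.fixture
def identity1():
    return TruthTable(1, [0, 1])


@pytest.fixture
def negation1():
    return TruthTable(1, [1, 0])


@pytest.fixture
def swap_network(identity1):
    """F(x1, x2) = (x2, x1)."""
    return BooleanNetwork(("a", "b"), ((1,), (0,)), (identity1, identity1))


@pytest.fixture
def identity_network():
    def make(n):
        tt = TruthTable(1, [0, 1])
        return BooleanNetwork(
            tuple(f"x{i}" for i in range(n)),
            tuple((i,) for i in range(n)),
            (tt,) * n,
        )

    return make


def enumerate_tables(k):
    """All 2^(2^k) truth tables on k inputs."""
    for code in range(1 << (1 << k)):
        yield TruthTable(k, [(code >> i) & 1 for i in range(1 << k)])


@pytest.fixture
def all_tables():
    return enumerate_tables
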