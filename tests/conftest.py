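import pytest

from indivevol.core import categorize_clock, packaged_fixture, read_trait_table
from indivevol.network import InteractionGraph, Partition


@pytest.fixture(scope="session")
def table1():
    return read_trait_table(packaged_fixture("table1"))


@pytest.fixture(scope="session")
def table4():
    return read_trait_table(packaged_fixture("table4"))


@pytest.fixture(scope="session")
def table4_clocked(table4):
    return categorize_clock(table4)


@pytest.fixture(scope="session")
def table5():
    return read_trait_table(packaged_fixture("table5"))


@pytest.fixture(scope="session")
def table5_clocked(table5):
    return categorize_clock(table5)


@pytest.fixture()
def two_triangles():
    """Two triangles joined by one bridge edge: a unique Q-optimal split."""
    g = InteractionGraph(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]
    )
    p = Partition({"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}, "planted")
    return g, p
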