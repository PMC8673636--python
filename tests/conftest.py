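import pytest

from pseudoid import NamePool, SyntheticNameSpec, generate_name_pool


@pytest.fixture(scope="session")
def big_pool() -> NamePool:
    """Phonebook-scale synthetic pool: 103,472 pairwise-distinct names."""
    return generate_name_pool(SyntheticNameSpec(size=103_472, seed=2021))


@pytest.fixture(scope="session")
def small_pool() -> NamePool:
    """A 2,000-name distinct pool for cheap unit tests."""
    return generate_name_pool(SyntheticNameSpec(size=2_000, seed=7))
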