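import numpy as np
import pytest

from txslip import SlippageSimParams, generate_genome, load_table1_fixture

BASES = "ACGT"


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


@pytest.fixture(scope="session")
def table1_records():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def small_genome():
    """A seeded ~40-gene genome with coverage, shared across tests."""
    params = SlippageSimParams(rng_seed=42)
    ann, cov = generate_genome(params, np.random.default_rng(42))
    return params, ann, cov


@pytest.fixture(scope="session")
def at_rich_genome():
    params = SlippageSimParams(gc_content=0.26, rng_seed=7)
    ann, cov = generate_genome(params, np.random.default_rng(7))
    return params, ann, cov
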