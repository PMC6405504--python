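import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stingless_ssd import load_bundled_table
from stingless_ssd.phylo_io import parse_tree

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def caste_table():
    return load_bundled_table()


@pytest.fixture
def cherry():
    return parse_tree("(A:1,B:1);")


@pytest.fixture
def three_taxon_tree():
    return parse_tree("((A:1,B:1):1,C:2);")


def spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, reproducible from a root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s) % 2**31 for s in ss.generate_state(n)]
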