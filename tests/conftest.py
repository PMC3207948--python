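import numpy as np
import pytest

from rwcoloc import GridSpec, generate_grid_pair


@pytest.fixture(scope="session")
def grid_pairs():
    """The 512x512 16-segment grid paired with each of its four rotations."""
    return {k: generate_grid_pair(GridSpec(rotation=k)) for k in range(4)}


@pytest.fixture()
def rng():
    return np.random.default_rng(20110407)


def random_pair(rng, max_side=8, lo=0, hi=255):
    """A random small channel pair for brute-force oracle comparisons."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    a = rng.integers(lo, hi + 1, (h, w)).astype(np.uint8)
    b = rng.integers(lo, hi + 1, (h, w)).astype(np.uint8)
    return a, b
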