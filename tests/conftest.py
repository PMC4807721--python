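import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_coords():
    """Five fixed, well-separated points in a 7 mm cube."""
    return np.array(
        [
            [0.5, 0.5, 0.5],
            [6.5, 0.5, 0.5],
            [0.5, 6.5, 0.5],
            [3.5, 3.5, 6.0],
            [2.0, 5.0, 2.5],
        ]
    )


def random_digraph(n: int, p: float, seed: int) -> np.ndarray:
    """Seeded random directed adjacency with empty diagonal (test helper)."""
    g = np.random.default_rng(seed)
    A = g.random((n, n)) < p
    np.fill_diagonal(A, False)
    return A
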