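import numpy as np
import pytest

from tectoquant.arbors import make_arbor


@pytest.fixture
def soma_only():
    return make_arbor([(1, None, 0.0, 0.0, 0.0)])


@pytest.fixture
def path_345():
    """Soma at origin, single child at (30, 40, 0): one 50 µm edge."""
    return make_arbor([(1, None, 0.0, 0.0, 0.0), (2, 1, 30.0, 40.0, 0.0)])


@pytest.fixture
def y_arbor():
    """Soma -> (0,0,10), branching to (0,±6,18); every edge is 10 µm."""
    return make_arbor(
        [
            (1, None, 0.0, 0.0, 0.0),
            (2, 1, 0.0, 0.0, 10.0),
            (3, 2, 0.0, 6.0, 18.0),
            (4, 2, 0.0, -6.0, 18.0),
        ]
    )


def straight_path(total_length: float, n_nodes: int = 2):
    """Unbranched radial arbor of exactly the given length along +x."""
    rows = [(1, None, 0.0, 0.0, 0.0)]
    for i in range(1, n_nodes):
        rows.append((i + 1, i, total_length * i / (n_nodes - 1), 0.0, 0.0))
    return make_arbor(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
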