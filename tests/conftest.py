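import numpy as np
import pytest

from caspectral import load_incidence


@pytest.fixture
def toy_table():
    """The 2x3 worked example: rows share the middle column."""
    return load_incidence(np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]]))


@pytest.fixture
def two_component_table():
    """Block-diagonal table whose similarity network has two components."""
    A = np.array(
        [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 1],
        ],
        dtype=float,
    )
    return load_incidence(A)


def random_table(seed, max_rows=40, max_cols=60, p=0.3):
    """Seeded random Bernoulli table (empty rows/cols dropped).

    Deliberately independent of the package's generators so it can probe
    the spectral identities on arbitrary, possibly disconnected tables.
    """
    rng = np.random.default_rng(seed)
    n_r = int(rng.integers(8, max_rows + 1))
    n_c = int(rng.integers(10, max_cols + 1))
    A = (rng.random((n_r, n_c)) < p).astype(float)
    return load_incidence(A, drop_empty=True)
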