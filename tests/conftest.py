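import numpy as np
import pytest

from bpbreathe import synthetic


@pytest.fixture(scope="session")
def wc_template():
    return synthetic.build_basepair_template("WC")


@pytest.fixture(scope="session")
def hg_template():
    return synthetic.build_basepair_template("HG")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
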