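import numpy as np
import pytest

from uaaff.fixtures import (
    make_binding_complex,
    make_esp_recovery_problem,
    make_toy_dipeptide,
)
from uaaff.pbsa import PbsaOptions


@pytest.fixture(scope="session")
def toy():
    return make_toy_dipeptide(seed=11)


@pytest.fixture(scope="session")
def esp_problem():
    return make_esp_recovery_problem(seed=11, n_atoms=4)


@pytest.fixture(scope="session")
def complex_small():
    return make_binding_complex(seed=11, n_res=3, n_snapshots=3)


@pytest.fixture(scope="session")
def fast_pb_options():
    """Coarse PB settings that keep toy-complex solves fast."""
    return PbsaOptions(grid_spacing=0.8, grid_padding=6.0, sasa_points=480)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
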