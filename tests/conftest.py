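import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chainfel as cf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def c11():
    return cf.ChainTopology(11)


@pytest.fixture(scope="session")
def params():
    return cf.PotentialParams()


@pytest.fixture(scope="session")
def warm_kernels():
    """Trigger numba compilation once so per-test timings stay honest."""
    from chainfel import _kernels

    phi = np.full(3, np.pi)
    coords = np.empty((6, 3))
    _kernels.chain_coords(phi, 1.53, np.deg2rad(112.7), coords)
    _kernels.mc_chunk(
        phi, 10, 5, 0.4, 1.53, np.deg2rad(112.7),
        np.asarray(cf.PotentialParams().torsion_coeffs), 0.39, 3.95, 3,
        False, 1.0, 1.0, 0.0, 0.0, 0.0, 0.5, 0.2, 1,
    )
    _kernels.ris_mc_chunk(
        np.zeros(3, dtype=np.int64), 10, 5, 0.4, 2.9, 8.0,
        np.ones(27), 0.0, 0.0, 1,
    )
    return True
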