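import numpy as np
import pytest

from coilgeom import (CrickParams, JunctionSpec, build_cable, build_ideal_dimer,
                      coiled_coil_profile, select_chain_trace)


@pytest.fixture(scope="session")
def params():
    return CrickParams()


@pytest.fixture(scope="session")
def ideal_dimer(params):
    return build_ideal_dimer(params, 161)


@pytest.fixture(scope="session")
def ideal_traces(ideal_dimer):
    return (select_chain_trace(ideal_dimer, "A"),
            select_chain_trace(ideal_dimer, "B"))


@pytest.fixture(scope="session")
def ideal_profile(ideal_traces):
    return coiled_coil_profile(*ideal_traces)


@pytest.fixture(scope="session")
def junction_spec():
    return JunctionSpec(twist_angle=90.0, overlap_length=8.0,
                        junction_width=15.0, n_dimers=3)


@pytest.fixture(scope="session")
def cable(params, junction_spec):
    return build_cable(params, junction_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    """A well-conditioned random rotation + translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-50, 50, 3)
    return R, t
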