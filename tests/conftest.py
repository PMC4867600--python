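import numpy as np
import pytest

from eitdct import (StimulationProtocol, assign_conductivity, build_mesh,
                    compute_jacobian, make_thorax_phantom, symmetric_disk_mesh)
from eitdct.pipeline import StudyConfig, build_suite


@pytest.fixture(scope="session")
def phantom():
    return make_thorax_phantom()


@pytest.fixture(scope="session")
def disk_mesh():
    return symmetric_disk_mesh(n_elec=16, n_rings=6)


@pytest.fixture(scope="session")
def protocol():
    return StimulationProtocol(n_elec=16)


@pytest.fixture(scope="session")
def small_mesh(phantom):
    """~300-element mesh of the default phantom for oracle sweeps."""
    return build_mesh(phantom, n_elec=16, target_n_elem=300)


@pytest.fixture(scope="session")
def small_jacobian(phantom, small_mesh, protocol):
    lin = assign_conductivity(small_mesh, phantom.lung_mask, phantom.extent,
                              0.5, 1.0)
    return lin, compute_jacobian(small_mesh, lin, protocol)


@pytest.fixture(scope="session")
def suite():
    """The default study suite: meshes, Jacobian, DCT basis, calibrated solvers."""
    return build_suite(StudyConfig())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160516)
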