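import numpy as np
import pytest

import mrnirst as mn
from mrnirst import forward_model as fm


@pytest.fixture(scope="session")
def acq():
    return mn.AcquisitionSpec()


@pytest.fixture(scope="session")
def coarse_mesh():
    # ~100 nodes: fast enough for repeated FEM solves in unit tests
    return mn.generate_mesh(40.0, 8.0)


@pytest.fixture(scope="session")
def coarse_layout(coarse_mesh):
    return mn.place_optodes(coarse_mesh, 16)


@pytest.fixture(scope="session")
def homog_state(coarse_mesh):
    return fm.ChromophoreState.uniform(coarse_mesh.n_nodes,
                                       mn.TissueProperties())


@pytest.fixture(scope="session")
def homog_data(coarse_mesh, coarse_layout, homog_state, acq):
    return fm.forward(homog_state, coarse_mesh, coarse_layout, acq)


@pytest.fixture(scope="session")
def fan_mesh():
    """Hand-built mirror-symmetric fan mesh: center node + 16 ring nodes."""
    theta = 2 * np.pi * np.arange(16) / 16
    ring = np.column_stack([40 * np.cos(theta), 40 * np.sin(theta)])
    nodes = np.vstack([ring, [[0.0, 0.0]]])
    elems = np.array([[k, (k + 1) % 16, 16] for k in range(16)])
    return mn.Mesh(nodes=nodes, elements=elems, boundary_nodes=np.arange(16))
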