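import numpy as np
import pytest

import softimpact as si


@pytest.fixture(scope="session")
def bar_mesh():
    """Small structured bar used across solver tests."""
    return si.generate_bar_mesh(0.1, 0.03, 0.03, (6, 2, 2))


@pytest.fixture(scope="session")
def tiny_bar():
    return si.generate_bar_mesh(0.1, 0.02, 0.02, (4, 1, 1))


@pytest.fixture(scope="session")
def small_ellipsoid():
    return si.generate_ellipsoid_mesh((0.09, 0.07, 0.08), 300, 0.0)


@pytest.fixture
def softening_material():
    return si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5, c_damping=12.0)


@pytest.fixture
def elastic_material():
    return si.ViscoelasticMaterial(E_modulus=25e6, c_damping=0.0, rho=1040.0)


def uniform_velocity(mesh, v):
    return np.tile(np.asarray(v, dtype=float), mesh.n_nodes)
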