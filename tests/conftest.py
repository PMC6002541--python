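import numpy as np
import pytest

from nanopnp.geometry import build_cylinder_pore
from nanopnp.mesh import MeshOptions, mesh_geometry
from nanopnp.molecule import generate_duplex


@pytest.fixture(scope="session")
def duplex20():
    return generate_duplex("AT" * 10, "B-DNA")


@pytest.fixture(scope="session")
def tiny_pore_geometry():
    return build_cylinder_pore(20.0, 20.0, 25.0)


@pytest.fixture(scope="session")
def tiny_pore_mesh(tiny_pore_geometry):
    opts = MeshOptions(res_pore=3.0, res_bulk=8.0, res_z_fine=3.0, res_z_bulk=8.0)
    return mesh_geometry(tiny_pore_geometry, options=opts)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
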