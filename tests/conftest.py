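import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_cube_mesh():
    """Single unit-cube element with trabecular label."""
    from femofall.materials import TissueCompartment
    from femofall.mesh import HexMesh

    nodes = np.array(
        [[x, y, z] for z in (0.0, 1.0) for y in (0.0, 1.0) for x in (0.0, 1.0)]
    )
    elements = np.array([[0, 1, 3, 2, 4, 5, 7, 6]])
    return HexMesh(
        nodes=nodes, elements=elements, compartment=[TissueCompartment.TRABECULAR]
    )


def make_bar_mesh(n_z=1, L=10.0, area_side=1.0):
    """Prismatic bar of n_z stacked unit-section elements along z."""
    from femofall.materials import TissueCompartment
    from femofall.mesh import HexMesh

    zs = np.linspace(0.0, L, n_z + 1)
    nodes = np.array(
        [[x, y, z] for z in zs for y in (0.0, area_side) for x in (0.0, area_side)]
    )
    elems = []
    for k in range(n_z):
        b = 4 * k
        elems.append([b, b + 1, b + 3, b + 2, b + 4, b + 5, b + 7, b + 6])
    return HexMesh(
        nodes=nodes,
        elements=np.array(elems),
        compartment=[TissueCompartment.TRABECULAR] * n_z,
    )


def bar_constraints(mesh, axis=np.array([0.0, 0.0, 1.0])):
    """Uniaxial-test constraints: base plane held, top face driven along z.

    Lateral contraction stays free so the stress state is exactly uniaxial.
    """
    from femofall.fe_solver import build_constraints

    zmax = mesh.nodes[:, 2].max()
    top = np.flatnonzero(np.isclose(mesh.nodes[:, 2], zmax))
    fixed = {
        0: (np.array([True, True, True]), np.zeros(3)),
        1: (np.array([False, True, True]), np.zeros(3)),
        2: (np.array([True, False, True]), np.zeros(3)),
        3: (np.array([False, False, True]), np.zeros(3)),
    }
    return build_constraints(mesh.n_nodes, fixed=fixed, prescribed=(top, axis))
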