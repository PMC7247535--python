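import numpy as np
import pytest

from brainmbm.geometry import (
    DEFAULT_PLANE_SPECS,
    Node,
    PlanarMesh,
    PlaneSpec,
    Spring,
    build_mesh,
)


@pytest.fixture(scope="session")
def coronal_mesh():
    return build_mesh(DEFAULT_PLANE_SPECS["coronal"])


@pytest.fixture(scope="session")
def small_spec():
    """A reduced ellipse with ~12 brain nodes, used for fast dynamics and
    calibration experiments."""
    return PlaneSpec("coronal", semi_axes=(0.060, 0.055), grid_spacing=0.028)


@pytest.fixture(scope="session")
def small_mesh(small_spec):
    return build_mesh(small_spec)


def make_oscillator(mass: float = 0.05, stiffness: float = 1000.0, length: float = 0.03) -> PlanarMesh:
    """One brain mass tethered to one fixed skull node: the analytic
    harmonic-oscillator toy."""
    spec = PlaneSpec("coronal", total_mass=mass, n_skull_nodes=3)
    nodes = [
        Node(0, "brain", np.array([0.0, 0.0]), mass),
        Node(1, "skull", np.array([length, 0.0])),
    ]
    springs = [Spring(0, 0, 1, stiffness, length)]
    mesh = PlanarMesh(spec=spec, nodes=nodes, springs=springs, triangles=[])
    mesh.validate(strict=False)
    return mesh


@pytest.fixture()
def oscillator_mesh():
    return make_oscillator()
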