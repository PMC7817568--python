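import numpy as np
import pytest

from sulcmorph.mesh import TriangleMesh, icosphere


@pytest.fixture(scope="session")
def ico3():
    return icosphere(3, radius=100.0)


@pytest.fixture(scope="session")
def ico4():
    return icosphere(4, radius=100.0)


@pytest.fixture(scope="session")
def template_left():
    from sulcmorph.simulate import make_template

    return make_template("left")


@pytest.fixture(scope="session")
def template_right():
    from sulcmorph.simulate import make_template

    return make_template("right")


@pytest.fixture
def chain_mesh():
    """Degenerate collinear triangle: edge lengths 1 (A-B), 2 (B-C), 3 (A-C).

    Geodesic A->C is 3 whichever path is taken, which makes hand-checked
    chain examples exact.
    """
    v = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
    f = np.array([[0, 1, 2]])
    return TriangleMesh(vertices=v, faces=f)


@pytest.fixture
def toy_sphere_mesh():
    """Small icosphere with sphere coordinates, for resampling tests."""
    return icosphere(2, radius=10.0)
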