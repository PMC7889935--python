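import numpy as np
import pytest

from spinedyn import membrane as mb


@pytest.fixture()
def params():
    return mb.MechanicalParams()


@pytest.fixture()
def unit_square():
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return mb.MembraneMesh(verts, np.zeros(4, dtype=np.int8),
                           h_psd=np.inf, h_neck=-np.inf)


def random_blob_mesh(rng, n=40, radius=0.4, noise=0.02):
    """Perturbed circle: a valid simple polygon for gradient checks."""
    m = mb.circle_mesh(radius, n)
    m.vertices += rng.normal(0.0, noise, m.vertices.shape)
    return m


@pytest.fixture()
def blob_factory():
    return random_blob_mesh
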