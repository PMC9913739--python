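import numpy as np
import pytest
import trimesh

from morphosurf import TriangleMesh, make_base_template


def icosphere(subdivisions: int = 2, radius: float = 1.0) -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices, dtype=float),
                        np.asarray(ico.faces, dtype=np.int64))


@pytest.fixture(scope="session")
def sphere2() -> TriangleMesh:
    """162-vertex unit icosphere."""
    return icosphere(2)


@pytest.fixture(scope="session")
def sphere1() -> TriangleMesh:
    """42-vertex unit icosphere."""
    return icosphere(1)


@pytest.fixture(scope="session")
def small_template():
    """Ellipsoid-head template: 162-vertex mesh, 12 landmarks, 30 semis."""
    return make_base_template("ellipsoid-head", subdivisions=2,
                              n_landmarks=12, k_semilandmarks=30)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
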