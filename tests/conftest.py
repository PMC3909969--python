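import numpy as np
import pytest
import trimesh

from bonemorph.mesh import TriangleMesh
from bonemorph.phantom import PhantomScenario, make_phantom


def icosphere_mesh(radius=10.0, subdivisions=3, center=(0.0, 0.0, 0.0)):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices) + np.asarray(center),
                        np.asarray(tm.faces))


@pytest.fixture(scope="session")
def sphere10():
    return icosphere_mesh(10.0, 3)


@pytest.fixture(scope="session")
def phantom96():
    """Default study conditions: 96^3 at 0.3 mm, blur 0.3 mm, noise 50."""
    return make_phantom(seed=5)


@pytest.fixture(scope="session")
def phantom96_clean():
    """Noise-free variant for sub-voxel accuracy checks."""
    return make_phantom(seed=5, noise_sigma=0.0)


@pytest.fixture(scope="session")
def scenario64():
    """Same anatomy on a coarser, faster lattice (64^3 at 0.45 mm)."""
    return PhantomScenario(shape=(64, 64, 64), spacing=0.45,
                           blur_sigma_mm=0.3)


@pytest.fixture(scope="session")
def phantom64(scenario64):
    return make_phantom(scenario64, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
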