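import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from gyriconn.geometry import icosphere
from gyriconn.morphometry import compute_outer_hull, compute_lgi
from gyriconn.synth import FoldSpec, generate_folded_surface


@pytest.fixture(scope="session")
def sphere4():
    """Subdivision-4 icosphere, radius 50 mm (2562 vertices)."""
    return icosphere(4, 50.0)


@pytest.fixture(scope="session")
def sphere3():
    return icosphere(3, 50.0)


@pytest.fixture(scope="session")
def sphere_hull(sphere4):
    """Outer hull of the plain sphere (shared: ~8 s to build)."""
    return compute_outer_hull(sphere4, closing_diameter=15.0, pitch=1.0)


@pytest.fixture(scope="session")
def folded_fixture():
    """Default folded surface with its hull and lGI map."""
    spec = FoldSpec()
    pial, white = generate_folded_surface(spec, seed=0)
    hull = compute_outer_hull(pial, closing_diameter=15.0, pitch=1.0)
    lgi = compute_lgi(pial, hull, radius=25.0)
    return {"spec": spec, "pial": pial, "white": white, "hull": hull, "lgi": lgi}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def patch_angles(surface, center=(1.0, 0.0, 0.0)):
    """Angular distance of each vertex direction from the patch centre."""
    u = surface.vertices / np.linalg.norm(surface.vertices, axis=1, keepdims=True)
    c = np.asarray(center) / np.linalg.norm(center)
    return np.arccos(np.clip(u @ c, -1.0, 1.0))
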