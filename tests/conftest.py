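import numpy as np
import pytest

from coralform import geometry as geo


@pytest.fixture(scope="session")
def unit_sphere():
    """Closed geodesic sphere, radius 1 m, ~2 cm-scale faces."""
    v, f = geo.geodesic_sphere(1.0, 8)
    return geo.TriSurface(v, f, np.zeros(len(v), dtype=bool))


@pytest.fixture(scope="session")
def colony_6cm():
    """The standard 6 cm seed colony clipped by the substratum."""
    return geo.make_initial_colony(0.06, 0.004)


def capsule_mask(pts, a, b, r):
    """Boolean mask of points within distance r of segment ab."""
    a = np.asarray(a, dtype=float)
    ab = np.asarray(b, dtype=float) - a
    t = np.clip(np.einsum("...c,c->...", pts - a, ab) / np.dot(ab, ab), 0, 1)
    return np.linalg.norm(pts - (a + t[..., None] * ab), axis=-1) <= r


@pytest.fixture(scope="session")
def voxel_grid_61():
    x = np.arange(61) + 0.5
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    return np.stack([X, Y, Z], axis=-1)
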