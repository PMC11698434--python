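import numpy as np
import pytest

from wingsym import SYM10_SCHEME, template_wing
from wingsym.synthetic import DiscPhantomParams, generate_disc_phantom


@pytest.fixture
def scheme():
    return SYM10_SCHEME


@pytest.fixture
def template():
    return template_wing()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless phantom small enough for fast pipeline tests (a=60, b=36)."""
    return generate_disc_phantom(
        DiscPhantomParams(image_shape=(160, 160), a=60.0, b=36.0, theta=0.3, noise_sd=0.0)
    )


def random_configuration(rng, n_points=10, spread=1.0):
    """A random non-degenerate landmark configuration."""
    from wingsym import LandmarkConfiguration

    coords = rng.normal(0.0, spread, size=(n_points, 2))
    labels = tuple(f"p{i}" for i in range(n_points))
    return LandmarkConfiguration(
        wing_id="rand", coords=coords, labels=labels, landmark_set="ML"
    )


def brute_force_disparity(x, y, coarse=4096, refine_iters=40):
    """Grid-search Procrustes disparity oracle.

    Standardizes both configurations (centroid at origin, unit Frobenius
    norm), then scans rotation angle densely for both proper and improper
    (reflected) orthogonal maps, using the analytic optimal scale per angle,
    and polishes the best angle by golden-section search.  Independent of the
    closed-form SVD route.
    """
    def standardize(m):
        m = np.asarray(m, dtype=float)
        m = m - m.mean(axis=0)
        return m / np.linalg.norm(m)

    X, Y = standardize(x), standardize(y)

    def disparity_at(theta, reflect):
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        if reflect:
            R = R @ np.array([[1.0, 0.0], [0.0, -1.0]])
        tr = float(np.sum(X * (Y @ R.T)))
        scale = max(tr, 0.0)  # analytic optimum of ||X - s*Y R^T||^2
        return 1.0 + scale**2 - 2.0 * scale * tr

    best = np.inf
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    for reflect in (False, True):
        thetas = np.linspace(0.0, 2.0 * np.pi, coarse, endpoint=False)
        vals = [disparity_at(t, reflect) for t in thetas]
        k = int(np.argmin(vals))
        lo = thetas[k] - 2.0 * np.pi / coarse
        hi = thetas[k] + 2.0 * np.pi / coarse
        a, b = lo, hi
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        for _ in range(refine_iters):
            if disparity_at(c, reflect) < disparity_at(d, reflect):
                b = d
            else:
                a = c
            c = b - gr * (b - a)
            d = a + gr * (b - a)
        best = min(best, disparity_at((a + b) / 2.0, reflect))
    return best
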