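import numpy as np
import pytest

from coatlattice import DensityMap


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def blob_template():
    """Asymmetric multi-Gaussian template in a 32^3 box (6 A voxels)."""
    n = 32
    zz, yy, xx = np.indices((n, n, n))
    c = (n - 1) / 2
    g = np.zeros((n, n, n))
    for dx, dy, dz, s, a in [
        (0, 0, 0, 3.0, 1.0),
        (5, 2, -1, 2.0, 0.8),
        (-4, 3, 4, 2.5, 0.6),
        (2, -6, 1, 1.5, 0.9),
    ]:
        g += a * np.exp(
            -(((xx - c - dx) ** 2 + (yy - c - dy) ** 2 + (zz - c - dz) ** 2) / (2 * s**2))
        )
    return DensityMap(g.astype(np.float32), 6.0)


def pearson(a, b):
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


@pytest.fixture
def corr():
    return pearson
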