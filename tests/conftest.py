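import numpy as np
import pytest

from chopct import phantom as ph
from chopct.types import BinaryMask


def dice(a, b) -> float:
    a = a.voxels if hasattr(a, "voxels") else a
    b = b.voxels if hasattr(b, "voxels") else b
    denom = np.count_nonzero(a) + np.count_nonzero(b)
    if denom == 0:
        return 1.0
    return 2 * np.count_nonzero(a & b) / denom


@pytest.fixture(scope="session")
def default_spec() -> ph.PhantomSpec:
    return ph.PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def phantom_out(default_spec):
    return ph.generate_embryo_phantom(default_spec)


@pytest.fixture(scope="session")
def noiseless_spec() -> ph.PhantomSpec:
    return ph.PhantomSpec(seed=1, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_out(noiseless_spec):
    return ph.generate_embryo_phantom(noiseless_spec)


def digitized_ball(radius: int, voxel_size_mm: float = 1.0, pad: int = 2) -> BinaryMask:
    n = 2 * (radius + pad) + 1
    c = (n - 1) / 2
    z, y, x = np.ogrid[:n, :n, :n]
    return BinaryMask(
        (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius**2, voxel_size_mm
    )


def digitized_ellipsoid(
    semi_axes, direction, shape=(96, 96, 96), voxel_size_mm: float = 1.0
) -> BinaryMask:
    """Ellipsoid with leading semi-axis along ``direction`` ((z,y,x) units)."""
    a, b, c = semi_axes
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    # orthonormal frame with first vector = direction
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(d, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(d, e2)
    centre = (np.array(shape) - 1) / 2
    idx = np.indices(shape).reshape(3, -1).T - centre
    u = idx @ d
    v = idx @ e2
    w = idx @ e3
    inside = (u / a) ** 2 + (v / b) ** 2 + (w / c) ** 2 <= 1.0
    return BinaryMask(inside.reshape(shape), voxel_size_mm)
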