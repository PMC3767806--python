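import numpy as np
import pytest

from wmfractal import PhantomSpec, make_phantom
from wmfractal.volume_io import ProbabilityVolume, VoxelGrid


@pytest.fixture(scope="session")
def menger3() -> VoxelGrid:
    """Level-3 Menger sponge on a 27^3 grid (8000 voxels)."""
    return make_phantom(PhantomSpec(kind="menger", level_or_size=3))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_blob_mask(seed: int, size: int = 40) -> np.ndarray:
    """Union of a few random balls; connected-ish test phantom."""
    r = np.random.default_rng(seed)
    g = np.zeros((size,) * 3, dtype=bool)
    zz, yy, xx = np.ogrid[:size, :size, :size]
    for _ in range(int(r.integers(2, 6))):
        c = r.integers(5, size - 5, 3)
        rad = int(r.integers(3, 8))
        g |= ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= rad**2
    return g


@pytest.fixture()
def gaussian_blob_volume() -> ProbabilityVolume:
    """Smooth anisotropic probability map (0.9 x 0.9 x 1.0 mm voxels)."""
    n = 40
    zz, yy, xx = np.mgrid[:n, :n, :n]
    c = (n - 1) / 2
    blob = np.exp(-(((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) / (2 * 8.0**2)))
    affine = np.diag([0.9, 0.9, 1.0, 1.0])
    return ProbabilityVolume(data=blob, affine=affine)
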