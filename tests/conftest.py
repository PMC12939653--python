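import numpy as np
import pytest

from vascsense.core import ImageVolume
from vascsense.phantom import NoiseModel, PhantomSpec, generate_vascular_phantom, simulate_kspace
from vascsense.topology import TopologyConfig


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=(96, 96), n_main_branches=5,
                       n_collateral_loops=2, seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_vascular_phantom(small_spec)


@pytest.fixture(scope="session")
def noisy_kspace(small_phantom):
    img, _ = small_phantom
    return simulate_kspace(img, NoiseModel(kspace_noise_sigma=0.06), seed=3)


@pytest.fixture(scope="session")
def topo_cfg():
    return TopologyConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def straight_tube_image(shape=(64, 64), row=32, sigma=1.2, peak=6.0,
                        voxel=0.5):
    """Horizontal bright tube on a unit background."""
    rr = np.arange(shape[0])[:, None]
    img = 1.0 + (peak - 1.0) * np.exp(-((rr - row) ** 2) / (2 * sigma**2))
    return ImageVolume(np.broadcast_to(img, shape).copy(), voxel)
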