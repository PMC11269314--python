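import numpy as np
import pytest

from oaskin.phantom import PhantomConfig, chow_like_config, hfd_sedentary_like_config

# Reduced acquisition geometry used by simulation-heavy tests: a 2 x 1 mm
# field at 15/30 µm raster steps with vessel diameters resolvable at that
# sampling.  Layer structure, baselines and densities are the package
# defaults.
SMALL_GEOMETRY = dict(
    fast_extent_mm=2.0,
    slow_extent_mm=1.0,
    voxel_size_mm=(0.01, 0.015, 0.03),
    depth_mm=2.5,
    diameter_ranges_um={"small": (30.0, 40.0), "large": (60.0, 150.0)},
)

# Even smaller field for tests that only need a valid phantom, not statistics.
TINY_GEOMETRY = dict(
    fast_extent_mm=0.6,
    slow_extent_mm=0.45,
    voxel_size_mm=(0.01, 0.015, 0.03),
    depth_mm=2.0,
    diameter_ranges_um={"small": (30.0, 40.0), "large": (60.0, 150.0)},
)


@pytest.fixture(scope="session")
def small_chow_config() -> PhantomConfig:
    return chow_like_config(**SMALL_GEOMETRY)


@pytest.fixture(scope="session")
def small_hfd_config() -> PhantomConfig:
    return hfd_sedentary_like_config(**SMALL_GEOMETRY)


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    return chow_like_config(**TINY_GEOMETRY)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
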