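import numpy as np
import pytest

from cristakit import RunConfig, make_crista_phantom, make_plate_pair, make_sphere


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def plate_pair():
    """Canonical persistence geometry: facing surfaces 4 voxels apart."""
    return make_plate_pair(separation_voxels=4, thickness_voxels=2, lateral_side=54)


@pytest.fixture(scope="session")
def crista_phantom():
    """Standard three-sheet lamellar phantom (width 6, spacing 6, 5 nm voxels)."""
    return make_crista_phantom(
        envelope_radius=26, sheet_width_voxels=6, sheet_spacing_voxels=6,
        n_sheets=3, roughness_amplitude_voxels=0.75, rng_seed=1,
    )


@pytest.fixture(scope="session")
def sphere_phantom():
    return make_sphere(radius_voxels=10, grid_side=26)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_blob_mask(rng, side):
    """Random smooth-ish binary mask for counting oracles."""
    from scipy import ndimage

    noise = rng.random((side, side, side))
    smooth = ndimage.gaussian_filter(noise, sigma=rng.uniform(0.8, 2.0))
    thr = np.quantile(smooth, rng.uniform(0.55, 0.8))
    return smooth > thr
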