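import numpy as np
import pytest

from orbitseg.phantom import default_params, generate_volume


@pytest.fixture(scope="session")
def ct_volume():
    """A small CT-style phantom with exact ground truth."""
    return generate_volume(default_params("ct", n_slices=5, seed=7))


@pytest.fixture(scope="session")
def mri_volume():
    return generate_volume(default_params("mri", n_slices=5, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_ring_map(shape, center, radius, thickness=3.0, blur=1.0):
    """A synthetic boundary-probability map: blurred ring of probability ~1."""
    import scipy.ndimage as ndi

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    rho = np.hypot(rr - center[0], cc - center[1])
    ring = (np.abs(rho - radius) <= thickness / 2).astype(float)
    if blur > 0:
        ring = ndi.gaussian_filter(ring, blur)
        ring /= max(ring.max(), 1e-9)
    return ring
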