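import numpy as np
import pytest

from swtreg import Image2D, PhantomSpec, make_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_phantom():
    """96x96 noiseless piecewise-constant phantom used across driver tests."""
    return make_phantom(PhantomSpec(shape=(96, 96), n_regions=5, seed=5))


@pytest.fixture()
def smooth_image(rng):
    """A smooth random field (band-limited), friendly to interpolation."""
    from scipy import ndimage

    return Image2D(ndimage.gaussian_filter(rng.normal(size=(64, 64)), 4.0) * 100.0)
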