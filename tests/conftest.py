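import warnings

import numpy as np
import pytest

from fundus2cfi.odscale import od_scale_adjust
from fundus2cfi.phantom import PhantomSpec, generate_phantom_pair

# MS-SSIM scale-count warnings are expected at desk image sizes
warnings.filterwarnings("ignore", message="image too small for 5 MS-SSIM scales")


@pytest.fixture(scope="session")
def pair3():
    """Phantom pair, seed 3, default (128 px) conditions."""
    return generate_phantom_pair(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def scaled3(pair3):
    """Scale-adjusted UFI of pair3, using the ground-truth OD box."""
    return od_scale_adjust(pair3.ufi, pair3.od_box_ufi, 128)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_homography(rng, scale=1.0, jitter=0.3):
    """A well-conditioned random homography for oracle tests."""
    H = np.eye(3)
    H[:2, :2] += rng.uniform(-jitter, jitter, (2, 2))
    H[:2, :2] *= scale
    H[:2, 2] = rng.uniform(-20, 20, 2)
    H[2, :2] = rng.uniform(-1e-3, 1e-3, 2)
    return H / H[2, 2]
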