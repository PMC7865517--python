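import numpy as np
import pytest

from focusfuse.synthetic import make_scene, random_scene, render_stack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    """Seeded non-constant [0,1] image, 64x64."""
    return rng.random((64, 64))


@pytest.fixture
def smooth_field(rng):
    """Smooth random field suitable for gradient-based registration."""
    from scipy import ndimage as ndi

    base = ndi.gaussian_filter(rng.random((96, 96)), 3.0)
    return (base - base.min()) / (base.max() - base.min())


@pytest.fixture(scope="session")
def synthetic_stack():
    """One deterministic 4-cell synthetic stack with ground truth."""
    spec = random_scene(4, size=64, seed=42)
    return render_stack(make_scene(spec))


def gradient_energy(img):
    gy, gx = np.gradient(img)
    return float(np.sum(gx * gx + gy * gy))
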