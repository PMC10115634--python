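import numpy as np
import pytest

from exsrrf.stacks_io import Image2D
from exsrrf.synthetic import SyntheticSpec, filament_emitters, make_emitter_stack


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def gaussian_blob():
    """A single symmetric Gaussian blob with a known subpixel centre."""
    yy, xx = np.mgrid[0:33, 0:33].astype(float)
    cy, cx = 16.3, 15.7
    data = 100.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 1.5**2))
    return Image2D(data), (cy, cx)


@pytest.fixture()
def drifting_stack():
    """Two-channel filamentous stack with a 0.3 px/frame drift, with truth."""
    spec = SyntheticSpec(
        image_shape=(48, 48),
        emitters=filament_emitters(7, shape=(48, 48), n_curves=3, margin_px=12.0),
        frames=12,
        drift_mode="linear",
        drift_rate=(0.3, 0.0),
        seed=7,
    )
    stack, truth = make_emitter_stack(spec)
    # duplicate the channel so multi-channel paths are exercised
    data = np.concatenate([stack.data, stack.data], axis=1)
    from exsrrf.stacks_io import TimeStack

    return TimeStack(data, pixel_size_nm=65.0), truth
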