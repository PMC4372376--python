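import numpy as np
import pytest

from necroscope import phantoms, quant

#: carrier aligned to the FFT grid of a 256-px image: no border wrap
#: discontinuity, so round-trip accuracy reflects the algorithms only
BIN_CARRIER_256 = (77 / 256, 77 / 256)


@pytest.fixture
def calib() -> quant.Calibration:
    return quant.Calibration()


@pytest.fixture
def small_spec() -> phantoms.PhantomSpec:
    return phantoms.PhantomSpec(
        image_shape=(160, 160), cell_count=1, n_frames=8, seed=11
    )


def gaussian_bump(shape=(256, 256), peak=8.0, sigma=25.0, center=None):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    if center is None:
        center = (shape[0] / 2, shape[1] / 2)
    return peak * np.exp(
        -(((yy - center[0]) ** 2 + (xx - center[1]) ** 2)) / (2 * sigma**2)
    )


@pytest.fixture
def bump_256():
    return gaussian_bump()
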