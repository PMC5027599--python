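import numpy as np
import pytest

import smlmbayes as sb


@pytest.fixture(scope="session")
def cam():
    return sb.standard_camera()


@pytest.fixture(scope="session")
def optics(cam):
    return sb.derive_optics(cam)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def make_spot_frame(optics, shape, x0, y0, n_psf, n_b):
    """Noiseless frame holding one Gaussian-model spot."""
    s0 = optics.s0_px
    ii, jj = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    vals = n_psf * np.exp(-((jj - x0) ** 2 + (ii - y0) ** 2) / (2 * s0 * s0)) / (
        2 * np.pi * s0 * s0
    ) + n_b
    return sb.PhotoelectronFrame(values=vals, frame_index=0)
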