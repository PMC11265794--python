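import numpy as np
import pytest

from mechwarp import erism, optics, warp


@pytest.fixture(scope="session")
def stack():
    return optics.default_stack()


@pytest.fixture(scope="session")
def grid():
    return optics.SpectrumGrid()


@pytest.fixture(scope="session")
def lookup(stack, grid):
    return optics.build_thickness_lookup(stack, grid, (8000.0, 10000.0), 1.0)


def model_calibration(stack, centre_nm=10000.0, span_fsr=1.5):
    """WARP calibration built from a forward-modelled thickness ramp."""
    n = stack.cavity_index(633.0).real
    fsr = 633.0 / (2.0 * n)
    ramp = np.tile(
        np.linspace(centre_nm - span_fsr * fsr / 2, centre_nm + span_fsr * fsr / 2, 96),
        (64, 1),
    )
    w = optics.warp_response(stack, ramp)
    s = optics.compute_reflectance(stack, 633.0, ramp) + optics.compute_reflectance(
        stack, 628.0, ramp
    )
    tmap = erism.ThicknessMap(ramp, 1.0, np.ones_like(ramp, dtype=bool))
    return warp.calibrate(w, tmap, sum_cal=s)


@pytest.fixture(scope="session")
def calibration(stack):
    return model_calibration(stack)


def flat_baseline(shape, thickness_nm=10000.0, pixel_size=1.0):
    return erism.ThicknessMap(
        np.full(shape, float(thickness_nm)), pixel_size, np.ones(shape, dtype=bool)
    )
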