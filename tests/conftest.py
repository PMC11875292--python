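"""Shared fixtures: synthetic acquisitions rendered on demand."""

import numpy as np
import pytest

from sfdiq import (
    LAPAROSCOPIC_FREQUENCIES,
    NoiseModel,
    OpticalProperties,
    ReferencePhantom,
    calibrate_reflectance,
    demodulate,
    flat_scene,
    render_reflectance_stack,
)


@pytest.fixture
def calibrated_factory():
    """Factory rendering a flat phantom through demod + calibration.

    Returns (CalibratedReflectance, truth_props).  The reference phantom
    is rendered noiselessly unless ref_noise is given.
    """

    def make(
        mua,
        musp,
        frequencies=LAPAROSCOPIC_FREQUENCIES,
        shape=(8, 8),
        noise=None,
        ref=(0.5, 10.0),
        ref_noise=None,
        n=1.4,
        wavelengths=None,
    ):
        kwargs = {"shape": shape, "n": n}
        if wavelengths is not None:
            kwargs["wavelengths"] = wavelengths
        scene = flat_scene(mua, musp, **kwargs)
        stack = render_reflectance_stack(scene, frequencies, noise=noise or NoiseModel())
        ref_scene = flat_scene(ref[0], ref[1], **kwargs)
        ref_stack = render_reflectance_stack(ref_scene, frequencies, noise=ref_noise or NoiseModel())
        dem = demodulate(stack)
        dem_ref = demodulate(ref_stack)
        ref_props = {b.center_nm: OpticalProperties(ref[0], ref[1], n) for b in dem.wavelengths}
        rd = calibrate_reflectance(dem, ReferencePhantom(ref_props, dem_ref))
        return rd, OpticalProperties(mua, musp, n)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
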