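"""Optical-property inversion: round trips, noise robustness across the
calibration-phantom range, brute-force grid-search equivalence, binning
and failure handling."""

import numpy as np
import pytest

from sfdiq import (
    LAPAROSCOPIC_FREQUENCIES,
    WIDEFIELD_FREQUENCIES,
    CalibratedReflectance,
    NoiseModel,
    WavelengthBand,
    bin_reflectance,
    diffuse_reflectance,
    fit_optical_properties,
)
from sfdiq.invert import DEFAULT_BOUNDS


def curve_as_calibrated(freqs, rd_values):
    """Wrap a single Rd(fx) curve as a 1-pixel CalibratedReflectance."""
    freqs = np.asarray(freqs, dtype=float)
    rd = np.asarray(rd_values, dtype=float)[:, None, None, None]
    return CalibratedReflectance(
        rd=rd,
        valid=np.isfinite(rd),
        frequencies=freqs,
        wavelengths=(WavelengthBand(660.0),),
    )


def test_noiseless_round_trip_five_frequencies():
    truth = (0.8, 15.0)
    rd = diffuse_reflectance(truth[0], truth[1], LAPAROSCOPIC_FREQUENCIES)
    opm = fit_optical_properties(curve_as_calibrated(LAPAROSCOPIC_FREQUENCIES, rd))
    assert opm.converged.all()
    assert opm.mua[0, 0, 0] == pytest.approx(truth[0], rel=1e-4)
    assert opm.musp[0, 0, 0] == pytest.approx(truth[1], rel=1e-4)


def test_phantom_grid_absorption_error_under_ten_percent(calibrated_factory):
    # 3x3 titration grid, 1% multiplicative noise, reference = (0.5, 10)
    errs = []
    for i, mua in enumerate((0.5, 1.0, 1.5)):
        for j, musp in enumerate((10.0, 20.0, 30.0)):
            if (mua, musp) == (0.5, 10.0):
                continue
            rd, props = calibrated_factory(
                mua, musp, shape=(32, 32),
                noise=NoiseModel(multiplicative_sigma=0.01, seed=100 + 10 * i + j),
            )
            opm = fit_optical_properties(rd, binning=8)
            assert opm.converged.all()
            errs.append(abs(np.nanmean(opm.mua) - mua) / mua * 100)
    assert np.mean(errs) < 10.0


def test_fit_agrees_with_dense_grid_search_oracle(rng):
    # brute-force 400x400 grid over the fit box: the continuous minimizer
    # must land within one grid cell of the discrete one
    mua_g = np.linspace(DEFAULT_BOUNDS[0][0], DEFAULT_BOUNDS[0][1], 400)
    musp_g = np.linspace(DEFAULT_BOUNDS[1][0], DEFAULT_BOUNDS[1][1], 400)
    cell = (mua_g[1] - mua_g[0], musp_g[1] - musp_g[0])
    grid_rd = diffuse_reflectance(
        mua_g[:, None, None], musp_g[None, :, None], LAPAROSCOPIC_FREQUENCIES[None, None, :]
    )
    for _ in range(10):
        truth_mua = rng.uniform(0.5, 1.5)
        truth_musp = rng.uniform(10.0, 30.0)
        y = diffuse_reflectance(truth_mua, truth_musp, LAPAROSCOPIC_FREQUENCIES)
        y = y * (1.0 + 0.01 * rng.standard_normal(y.shape))
        cost = ((grid_rd - y) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(cost), cost.shape)
        opm = fit_optical_properties(curve_as_calibrated(LAPAROSCOPIC_FREQUENCIES, y))
        assert abs(opm.mua[0, 0, 0] - mua_g[i]) <= cell[0]
        assert abs(opm.musp[0, 0, 0] - musp_g[j]) <= cell[1]


def test_recovery_fifty_random_pairs_widefield(rng):
    # median absolute percent error < 5% for both parameters at 1% noise
    # with the 22-frequency configuration
    ape_mua, ape_musp = [], []
    for _ in range(50):
        mua = rng.uniform(0.5, 1.5)
        musp = rng.uniform(10.0, 30.0)
        y = diffuse_reflectance(mua, musp, WIDEFIELD_FREQUENCIES)
        y = y * (1.0 + 0.01 * rng.standard_normal(y.shape))
        opm = fit_optical_properties(curve_as_calibrated(WIDEFIELD_FREQUENCIES, y))
        ape_mua.append(abs(opm.mua[0, 0, 0] - mua) / mua * 100)
        ape_musp.append(abs(opm.musp[0, 0, 0] - musp) / musp * 100)
    assert np.median(ape_mua) < 5.0
    assert np.median(ape_musp) < 5.0


@pytest.mark.parametrize("freqs", [WIDEFIELD_FREQUENCIES, LAPAROSCOPIC_FREQUENCIES])
def test_frequency_set_robustness(freqs, rng):
    # both instrument configurations recover properties within 10% at 1% noise
    for mua, musp in [(0.5, 30.0), (1.5, 10.0), (1.0, 20.0)]:
        y = diffuse_reflectance(mua, musp, freqs)
        y = y * (1.0 + 0.01 * rng.standard_normal(y.shape))
        opm = fit_optical_properties(curve_as_calibrated(freqs, y))
        assert abs(opm.mua[0, 0, 0] - mua) / mua < 0.10
        assert abs(opm.musp[0, 0, 0] - musp) / musp < 0.10


def test_determinism_bit_identical(calibrated_factory):
    rd, _ = calibrated_factory(1.0, 20.0, shape=(8, 8), noise=NoiseModel(multiplicative_sigma=0.01, seed=7))
    a = fit_optical_properties(rd, binning=4)
    b = fit_optical_properties(rd, binning=4)
    assert np.array_equal(a.mua, b.mua) and np.array_equal(a.musp, b.musp)


def test_too_few_frequencies_marks_unconverged():
    rd = curve_as_calibrated([0.0, 0.5, 1.0], diffuse_reflectance(1.0, 20.0, [0.0, 0.5, 1.0]))
    rd.valid[1:, 0, 0, 0] = False
    rd.rd[1:] = np.nan
    opm = fit_optical_properties(rd)
    assert not opm.converged[0, 0, 0]
    assert np.isnan(opm.mua[0, 0, 0])


def test_masked_pixels_propagate(calibrated_factory):
    rd, _ = calibrated_factory(1.0, 20.0, shape=(4, 4))
    rd.valid[:, 0, 1, 2] = False
    rd.rd[:, 0, 1, 2] = np.nan
    opm = fit_optical_properties(rd)
    assert not opm.converged[0, 1, 2]
    assert np.isnan(opm.mua[0, 1, 2]) and np.isnan(opm.musp[0, 1, 2])
    assert opm.converged[0, 0, 0]


def test_prescan_matches_default_on_benign_curve():
    y = diffuse_reflectance(1.3, 25.0, LAPAROSCOPIC_FREQUENCIES)
    a = fit_optical_properties(curve_as_calibrated(LAPAROSCOPIC_FREQUENCIES, y))
    b = fit_optical_properties(curve_as_calibrated(LAPAROSCOPIC_FREQUENCIES, y), prescan=True)
    assert a.mua[0, 0, 0] == pytest.approx(b.mua[0, 0, 0], rel=1e-6)


def test_invalid_bounds_rejected():
    y = diffuse_reflectance(1.0, 20.0, LAPAROSCOPIC_FREQUENCIES)
    with pytest.raises(ValueError, match="bounds"):
        fit_optical_properties(curve_as_calibrated(LAPAROSCOPIC_FREQUENCIES, y), bounds=((1.0, 0.5), (1.0, 100.0)))


class TestBinning:
    def test_mean_pooling_hand_case(self):
        rd_map = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
        cal = CalibratedReflectance(
            rd=rd_map, valid=np.ones_like(rd_map, bool),
            frequencies=np.array([0.0]), wavelengths=(WavelengthBand(660.0),),
        )
        pooled = bin_reflectance(cal, 2)
        expected = np.array([[2.5, 4.5], [10.5, 12.5]])
        np.testing.assert_allclose(pooled.rd[0, 0], expected)

    def test_nan_aware_pooling(self):
        rd_map = np.ones((1, 1, 2, 2))
        rd_map[0, 0, 0, 0] = np.nan
        valid = np.isfinite(rd_map)
        cal = CalibratedReflectance(
            rd=rd_map, valid=valid, frequencies=np.array([0.0]), wavelengths=(WavelengthBand(660.0),),
        )
        pooled = bin_reflectance(cal, 2)
        assert pooled.rd[0, 0, 0, 0] == pytest.approx(1.0)
        assert pooled.valid[0, 0, 0, 0]

    def test_factor_one_is_identity(self):
        rd_map = np.ones((1, 1, 3, 3))
        cal = CalibratedReflectance(
            rd=rd_map, valid=np.ones_like(rd_map, bool),
            frequencies=np.array([0.0]), wavelengths=(WavelengthBand(660.0),),
        )
        assert bin_reflectance(cal, 1) is cal

    def test_bad_factor_rejected(self):
        rd_map = np.ones((1, 1, 3, 3))
        cal = CalibratedReflectance(
            rd=rd_map, valid=np.ones_like(rd_map, bool),
            frequencies=np.array([0.0]), wavelengths=(WavelengthBand(660.0),),
        )
        with pytest.raises(ValueError):
            bin_reflectance(cal, 0)
        with pytest.raises(ValueError):
            bin_reflectance(cal, 5)
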