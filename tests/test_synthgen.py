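"""Synthetic-acquisition generator: construction identities, seeded
determinism, noise magnitude against an error-propagation oracle, and the
contrast-inversion scene."""

import numpy as np
import pytest

from sfdiq import (
    DOX_CALIBRATION_UG_ML,
    LAPAROSCOPIC_FREQUENCIES,
    WIDEFIELD_FREQUENCIES,
    NoiseModel,
    OpticalProperties,
    ReferencePhantom,
    calibrate_reflectance,
    correct_fluorescence,
    correction_factor,
    demodulate,
    diffuse_reflectance,
    flat_scene,
    make_phantom_suite,
    render_fluorescence_frame,
    render_reflectance_stack,
    subtract_autofluorescence,
    to_concentration,
    tumor_scene,
    fit_calibration,
)

REF = OpticalProperties(0.5, 10.0)


class TestReflectanceRendering:
    def test_noiseless_demodulation_recovers_gain_times_rd(self):
        scene = flat_scene(1.0, 20.0, shape=(8, 8))
        stack = render_reflectance_stack(scene, LAPAROSCOPIC_FREQUENCIES)
        dem = demodulate(stack)
        expected = stack.meta["gain"] * diffuse_reflectance(1.0, 20.0, LAPAROSCOPIC_FREQUENCIES)
        np.testing.assert_allclose(
            dem.mac, np.broadcast_to(expected[:, None, None, None], dem.mac.shape), rtol=1e-10
        )

    def test_heterogeneous_scene_per_pixel(self):
        scene = tumor_scene(shape=(16, 16), radius=4)
        stack = render_reflectance_stack(scene, [0.0, 1.0])
        dem = demodulate(stack)
        g = stack.meta["gain"]
        rd_truth = diffuse_reflectance(scene.mua[0], scene.musp[0], 1.0)
        np.testing.assert_allclose(dem.mac[1, 0], g * rd_truth, rtol=1e-10)

    def test_same_seed_bit_identical_different_seed_differs(self):
        scene = flat_scene(1.0, 20.0, shape=(8, 8))
        n1 = NoiseModel(multiplicative_sigma=0.01, seed=5)
        a = render_reflectance_stack(scene, LAPAROSCOPIC_FREQUENCIES, noise=n1)
        b = render_reflectance_stack(scene, LAPAROSCOPIC_FREQUENCIES, noise=NoiseModel(0.01, seed=5))
        c = render_reflectance_stack(scene, LAPAROSCOPIC_FREQUENCIES, noise=NoiseModel(0.01, seed=6))
        assert np.array_equal(a.images, b.images)
        assert not np.array_equal(a.images, c.images)

    def test_nyquist_violation_rejected(self):
        scene = flat_scene(1.0, 20.0, shape=(8, 8))
        with pytest.raises(ValueError, match="Nyquist"):
            render_reflectance_stack(scene, [0.0, 25.0], pixels_per_cm=40.0)

    def test_noise_magnitude_matches_propagation_oracle(self):
        # first-order error propagation of per-frame multiplicative noise
        # through the three-phase estimator predicts std(M_AC); the
        # rendered stacks must agree within 20%
        sigma = 0.01
        scene = flat_scene(1.0, 20.0, shape=(128, 128))
        clean = render_reflectance_stack(scene, LAPAROSCOPIC_FREQUENCIES).images
        noisy = render_reflectance_stack(
            scene, LAPAROSCOPIC_FREQUENCIES, noise=NoiseModel(multiplicative_sigma=sigma, seed=11)
        ).images
        for fi in range(LAPAROSCOPIC_FREQUENCIES.size):
            i1, i2, i3 = clean[:, fi, 0]
            d12, d23, d31 = i1 - i2, i2 - i3, i3 - i1
            u = d12**2 + d23**2 + d31**2
            mac_clean = np.sqrt(2.0) / 3.0 * np.sqrt(u)
            grads = [
                np.sqrt(2.0) / 3.0 * (d12 - d31) / np.sqrt(u),
                np.sqrt(2.0) / 3.0 * (d23 - d12) / np.sqrt(u),
                np.sqrt(2.0) / 3.0 * (d31 - d23) / np.sqrt(u),
            ]
            var_pred = sum(g**2 * (sigma * i) ** 2 for g, i in zip(grads, [i1, i2, i3]))
            predicted_std = float(np.sqrt(var_pred).mean())

            n1, n2, n3 = noisy[:, fi, 0]
            mac_noisy = np.sqrt(2.0) / 3.0 * np.sqrt(
                (n1 - n2) ** 2 + (n2 - n3) ** 2 + (n3 - n1) ** 2
            )
            measured_std = float((mac_noisy - mac_clean).std())
            assert measured_std == pytest.approx(predicted_std, rel=0.20)

    def test_dark_level_added_and_reported(self):
        scene = flat_scene(1.0, 20.0, shape=(8, 8))
        stack = render_reflectance_stack(scene, LAPAROSCOPIC_FREQUENCIES, dark_level=100.0)
        assert stack.dark is not None
        np.testing.assert_allclose(stack.dark, 100.0)
        dem = demodulate(stack)  # dark subtraction restores the clean AC
        g = stack.meta["gain"]
        expected = g * diffuse_reflectance(1.0, 20.0, LAPAROSCOPIC_FREQUENCIES)
        np.testing.assert_allclose(
            dem.mac, np.broadcast_to(expected[:, None, None, None], dem.mac.shape), rtol=1e-9
        )


class TestPhantomSuite:
    def test_grid_layout_and_truth(self):
        suite = make_phantom_suite(shape=(4, 4))
        assert len(suite) == 9
        assert suite[0][1] == OpticalProperties(0.5, 10.0, 1.4)
        assert suite[-1][1] == OpticalProperties(1.5, 30.0, 1.4)

    def test_single_point_grid_self_calibrates_exactly(self):
        suite = make_phantom_suite(mua_values=[1.0], musp_values=[20.0], shape=(4, 4))
        assert len(suite) == 1
        stack, props = suite[0]
        dem = demodulate(stack)
        phantom = ReferencePhantom({660.0: props}, dem)
        rd = calibrate_reflectance(dem, phantom)
        expected = diffuse_reflectance(props.mua, props.musp, rd.frequencies)
        np.testing.assert_allclose(
            rd.rd, np.broadcast_to(expected[:, None, None, None], rd.rd.shape), rtol=1e-12
        )

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            make_phantom_suite(mua_values=[], musp_values=[10.0])

    def test_suite_reproducible_from_seed(self):
        a = make_phantom_suite(shape=(4, 4), noise=NoiseModel(0.01, seed=3))
        b = make_phantom_suite(shape=(4, 4), noise=NoiseModel(0.01, seed=3))
        for (sa, _), (sb, _) in zip(a, b):
            assert np.array_equal(sa.images, sb.images)

    def test_widefield_and_laparoscopic_frequency_sets(self):
        assert WIDEFIELD_FREQUENCIES.size == 22
        assert WIDEFIELD_FREQUENCIES[-1] == pytest.approx(3.1764)
        assert LAPAROSCOPIC_FREQUENCIES.size == 5
        assert LAPAROSCOPIC_FREQUENCIES[-1] == pytest.approx(2.5)


class TestFluorescenceRendering:
    CAL = (150.0, 0.0)

    def test_zero_concentration_zero_background_equals_dark(self):
        scene = flat_scene(0.5, 10.0, shape=(6, 6), fluor=0.0)
        f_raw, dark = render_fluorescence_frame(scene, 0, 0, self.CAL, REF, REF)
        np.testing.assert_allclose(f_raw, dark)

    def test_round_trip_under_calibration_optics(self):
        # C = 5 ug/mL with phantom-matched optics: exact noiseless recovery
        scene = flat_scene(0.5, 10.0, shape=(6, 6), fluor=5.0)
        f_raw, dark = render_fluorescence_frame(scene, 0, 0, self.CAL, REF, REF)
        x1d = correction_factor(scene.mua[0], scene.musp[0], scene.mua[0], scene.musp[0], REF, REF)
        f_corr = correct_fluorescence(f_raw, dark, x1d)
        cal = fit_calibration(list(DOX_CALIBRATION_UG_ML), [self.CAL[0] * c for c in DOX_CALIBRATION_UG_ML])
        conc = to_concentration(f_corr, cal)
        np.testing.assert_allclose(conc, 5.0, rtol=1e-10)

    def test_full_chain_with_background_recovers_truth(self):
        scene = tumor_scene(shape=(16, 16), radius=4, fluor_tumor=6.0, fluor_periphery=2.0,
                            background_fluor=40.0)
        f_raw, dark = render_fluorescence_frame(scene, 0, 1, self.CAL, REF, REF)
        bg_scene = tumor_scene(shape=(16, 16), radius=4, fluor_tumor=0.0, fluor_periphery=0.0,
                               background_fluor=40.0)
        bg_raw, bg_dark = render_fluorescence_frame(bg_scene, 0, 1, self.CAL, REF, REF)
        x1d = correction_factor(scene.mua[0], scene.musp[0], scene.mua[1], scene.musp[1], REF, REF)
        f_corr = correct_fluorescence(f_raw, dark, x1d)
        bg_corr = correct_fluorescence(bg_raw, bg_dark, x1d)
        f_signal, _ = subtract_autofluorescence(f_corr, bg_corr)
        cal = fit_calibration(list(DOX_CALIBRATION_UG_ML), [self.CAL[0] * c for c in DOX_CALIBRATION_UG_ML])
        conc = to_concentration(f_signal, cal)
        np.testing.assert_allclose(conc, scene.fluor, rtol=1e-9, atol=1e-9)

    def test_tumor_raw_contrast_inverts_while_x1d_explains_it(self):
        # the attenuation penalty X_1D(tumor)/X_1D(periphery) must exceed
        # the concentration excess for the designed default scene
        scene = tumor_scene(shape=(32, 32), radius=8)
        disc = scene.fluor == scene.fluor.max()
        x1d = correction_factor(scene.mua[0], scene.musp[0], scene.mua[1], scene.musp[1], REF, REF)
        x_ratio = x1d[disc].mean() / x1d[~disc].mean()
        c_ratio = scene.fluor[disc].mean() / scene.fluor[~disc].mean()
        assert x_ratio * c_ratio < 1.0 < c_ratio
        f_raw, dark = render_fluorescence_frame(scene, 0, 1, self.CAL, REF, REF)
        net = f_raw - dark
        assert net[disc].mean() < net[~disc].mean()  # inverted raw contrast

    def test_seeded_fluorescence_noise_reproducible(self):
        scene = flat_scene(0.5, 10.0, shape=(6, 6), fluor=5.0)
        nm = NoiseModel(multiplicative_sigma=0.02, read_sigma=1.0, seed=9)
        a, _ = render_fluorescence_frame(scene, 0, 0, self.CAL, REF, REF, noise=nm)
        b, _ = render_fluorescence_frame(scene, 0, 0, self.CAL, REF, REF, noise=NoiseModel(0.02, 1.0, seed=9))
        assert np.array_equal(a, b)

    def test_scene_validation(self):
        with pytest.raises(ValueError, match="fluor"):
            scene = flat_scene(0.5, 10.0, shape=(4, 4))
            scene.fluor = None
            render_fluorescence_frame(scene, 0, 0, self.CAL, REF, REF)
        with pytest.raises(ValueError, match="slope"):
            render_fluorescence_frame(flat_scene(0.5, 10.0, shape=(4, 4), fluor=1.0), 0, 0, (0.0, 0.0), REF, REF)
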