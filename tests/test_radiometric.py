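"""Empirical-line calibration fits, application, and histogram equalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from turfscreen import (
    PanelObservation,
    SceneParams,
    apply_calibration,
    equalize_histogram,
    fit_empirical_line,
    generate_scene,
    panel_observations,
)
from turfscreen.errors import ConfigError, InsufficientPanelsError
from turfscreen.scenesim import MS_BANDS


def panels(band, pairs):
    return [PanelObservation(band=band, reflectance=r, dn=dn) for dn, r in pairs]


class TestEmpiricalLineFit:
    def test_two_point_linear_solution(self):
        model = fit_empirical_line(panels("nir", [(0.0, 0.0), (200.0, 1.0)]))
        assert model.gain == pytest.approx(0.005)
        assert model.bias == pytest.approx(0.0, abs=1e-12)

    def test_linear_matches_closed_form_least_squares(self):
        # 4 panels with noise baked in; oracle = closed-form simple regression
        dn = np.array([20.0, 50.0, 91.0, 128.0])
        refl = np.array([0.05, 0.2, 0.4, 0.6])
        model = fit_empirical_line(panels("red", zip(dn, refl)))
        sxx = ((dn - dn.mean()) ** 2).sum()
        sxy = ((dn - dn.mean()) * (refl - refl.mean())).sum()
        assert model.gain == pytest.approx(sxy / sxx, rel=1e-12)
        assert model.bias == pytest.approx(refl.mean() - sxy / sxx * dn.mean(), rel=1e-10)

    def test_zero_dn_spread_rejected(self):
        with pytest.raises(InsufficientPanelsError):
            fit_empirical_line(panels("nir", [(100.0, 0.25), (100.0, 0.75)]))

    def test_single_panel_rejected(self):
        with pytest.raises(InsufficientPanelsError):
            fit_empirical_line(panels("nir", [(100.0, 0.5)]))

    def test_exponential_exact_recovery(self):
        a, b = 20.0, 3.0
        refl = np.array([0.1, 0.3, 0.5, 0.7])
        dn = a * np.exp(b * refl)
        model = fit_empirical_line(panels("rgb-green", zip(dn, refl)),
                                   form="exponential")
        assert model.a == pytest.approx(a, rel=1e-6)
        assert model.b == pytest.approx(b, rel=1e-6)

    def test_exponential_rejects_nonpositive_dn(self):
        with pytest.raises(InsufficientPanelsError):
            fit_empirical_line(panels("rgb-red", [(0.0, 0.1), (50.0, 0.5)]),
                               form="exponential")

    def test_parameter_recovery_under_panel_noise(self):
        # panel DN summarized as a mean over a 48x48 panel of noisy pixels
        rng = np.random.default_rng(21)
        refl = np.array([0.05, 0.15, 0.3, 0.45, 0.6, 0.75])
        n_px = 48 * 48
        for _ in range(20):
            dn_mean = 200.0 * refl + 10.0 + rng.normal(0, 1.0, refl.size) / np.sqrt(n_px)
            model = fit_empirical_line(panels("nir", zip(dn_mean, refl)))
            assert model.gain == pytest.approx(1 / 200.0, rel=0.01)
            assert model.bias == pytest.approx(-10.0 / 200.0, rel=0.01)


class TestApplyCalibration:
    def test_constant_raster_linear(self):
        model = fit_empirical_line(panels("nir", [(0.0, 0.0), (200.0, 1.0)]))
        out = apply_calibration(np.full((4, 4), 100.0), model)
        np.testing.assert_allclose(out, 0.5)

    def test_clipped_to_unit_interval(self):
        model = fit_empirical_line(panels("nir", [(0.0, 0.0), (200.0, 1.0)]))
        assert apply_calibration(np.array([[240.0]]), model)[0, 0] == 1.0

    def test_exponential_marks_nonpositive_dn_invalid(self):
        model = fit_empirical_line(
            panels("rgb-red", [(20.0, 0.1), (60.0, 0.5)]), form="exponential"
        )
        out = apply_calibration(np.array([[0.0, 30.0]]), model)
        assert np.isnan(out[0, 0]) and np.isfinite(out[0, 1])

    def test_band_mismatch_rejected(self):
        model = fit_empirical_line(panels("nir", [(0.0, 0.0), (200.0, 1.0)]))
        with pytest.raises(ConfigError):
            apply_calibration(np.zeros((2, 2)), model, band="red")

    def test_monotone_in_dn(self):
        linear = fit_empirical_line(panels("nir", [(10.0, 0.1), (150.0, 0.7)]))
        expo = fit_empirical_line(
            panels("rgb-red", [(20.0, 0.1), (90.0, 0.5), (200.0, 0.8)]),
            form="exponential",
        )
        dn = np.linspace(1, 200, 100).reshape(1, -1)
        for model in (linear, expo):
            out = apply_calibration(dn, model).ravel()
            assert (np.diff(out) >= 0).all()

    def test_noiseless_scene_round_trip_within_one_dn(self, noiseless_scene):
        stack, truth = noiseless_scene
        step = 1.0 / stack.params.ms_gain
        for band in MS_BANDS:
            if band == "red":
                continue  # content displaced; covered by the alignment tests
            obs = panel_observations(stack.bands[band], band, stack.panels)
            model = fit_empirical_line(obs)
            recovered = apply_calibration(stack.bands[band], model)
            err = np.abs(recovered - truth.reflectance[band])
            assert np.nanmax(err) <= step + 1e-9


class TestHistogramEqualization:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 77, dtype=np.uint8)
        np.testing.assert_array_equal(equalize_histogram(img), img)

    def test_two_level_image_maps_to_extremes(self):
        img = np.concatenate([np.full(50, 10), np.full(50, 20)]).astype(np.uint8)
        out = equalize_histogram(img.reshape(10, 10))
        assert set(np.unique(out)) == {0, 255}
        assert (out.ravel()[:50] == 0).all() and (out.ravel()[50:] == 255).all()

    @given(st.integers(0, 2**31 - 1))
    def test_mapping_preserves_rank_order(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        out = equalize_histogram(img)
        a, b = img.ravel().astype(int), out.ravel().astype(int)
        order = np.argsort(a, kind="stable")
        assert (np.diff(b[order]) >= 0).all()
        # equal input levels must map to equal output levels
        for level in np.unique(a):
            assert len(np.unique(b[a == level])) == 1

    def test_rgb_equalized_per_channel(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 40, size=(12, 12, 3), dtype=np.uint8)
        out = equalize_histogram(img)
        assert out.shape == img.shape
        assert out.max() == 255  # dark image stretched to full range

    def test_non_uint8_rejected(self):
        with pytest.raises(ConfigError):
            equalize_histogram(np.zeros((4, 4), dtype=np.uint16))
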