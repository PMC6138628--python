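"""Integrated density, ROI splitting and calibration curves."""

import numpy as np
import pytest

from pepmem import (
    VesselImage,
    fit_calibration,
    inside_outside_split,
    integrated_density,
    invert_calibration,
    percent_delivered,
    predict_density,
    threshold_nonzero,
)
from pepmem.errors import DegenerateInputError, OutOfRangeError
from pepmem.synthetic_data import gen_brain_image


def _image(pixels, mask=None, area=1.0):
    pixels = np.asarray(pixels, dtype=float)
    if mask is None:
        mask = np.zeros_like(pixels, dtype=bool)
        mask[0, 0] = True  # placeholder vessel
    return VesselImage(pixels=pixels, vessel_mask=mask, pixel_area_um2=area)


class TestThresholdNonzero:
    def test_all_zero_image_yields_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            mask = threshold_nonzero(_image(np.zeros((8, 8))))
        assert not mask.any()

    def test_positive_method_on_binary_image(self):
        px = np.zeros((10, 10))
        px[2:4, 2:4] = 100.0
        mask = threshold_nonzero(_image(px), method="positive")
        np.testing.assert_array_equal(mask, px == 100.0)

    def test_otsu_separates_bimodal_background_and_signal(self):
        rng = np.random.default_rng(0)
        px = rng.normal(5.0, 1.0, (64, 64))
        signal = np.zeros((64, 64), dtype=bool)
        signal[20:40, 20:40] = True
        px[signal] = rng.normal(100.0, 5.0, signal.sum())
        px = np.clip(px, 0, None)
        mask = threshold_nonzero(_image(px), method="otsu")
        recall = (mask & signal).sum() / signal.sum()
        assert recall >= 0.99


class TestIntegratedDensity:
    def test_uniform_region(self):
        px = np.full((10, 10), 10.0)
        roi = np.zeros((10, 10), dtype=bool)
        roi[:10, :10] = True
        d = integrated_density(_image(px), roi)
        assert (d.mean_fluorescence, d.area_um2, d.integrated_density) == (
            10.0,
            100.0,
            1000.0,
        )

    def test_single_pixel(self):
        px = np.zeros((4, 4))
        px[1, 2] = 7.5
        roi = np.zeros((4, 4), dtype=bool)
        roi[1, 2] = True
        d = integrated_density(_image(px, area=0.76), roi)
        assert d.integrated_density == pytest.approx(7.5 * 0.76)

    def test_checkerboard(self):
        px = np.indices((20, 10)).sum(axis=0) % 2 * 20.0  # alternating 0/20
        roi = np.ones((20, 10), dtype=bool)
        d = integrated_density(_image(px), roi)
        assert d.mean_fluorescence == pytest.approx(10.0)
        assert d.integrated_density == pytest.approx(2000.0)

    def test_empty_roi_raises(self):
        with pytest.raises(DegenerateInputError):
            integrated_density(_image(np.ones((4, 4))), np.zeros((4, 4), bool))

    def test_additive_over_disjoint_rois(self):
        rng = np.random.default_rng(1)
        px = rng.uniform(0, 50, (32, 32))
        a = np.zeros((32, 32), bool)
        b = np.zeros((32, 32), bool)
        a[:16], b[16:] = True, True
        img = _image(px, area=0.76)
        ida = integrated_density(img, a).integrated_density
        idb = integrated_density(img, b).integrated_density
        idu = integrated_density(img, a | b).integrated_density
        assert ida + idb == pytest.approx(idu, rel=1e-12)

    def test_scales_linearly_with_intensity_and_pixel_area(self):
        px = np.random.default_rng(2).uniform(1, 5, (8, 8))
        roi = np.ones((8, 8), bool)
        base = integrated_density(_image(px), roi).integrated_density
        assert integrated_density(_image(3 * px), roi).integrated_density == (
            pytest.approx(3 * base)
        )
        assert integrated_density(_image(px, area=2.0), roi).integrated_density == (
            pytest.approx(2 * base)
        )


class TestInsideOutsideSplit:
    def test_signal_only_inside_vessels_gives_zero_outside(self):
        px = np.zeros((16, 16))
        mask = np.zeros((16, 16), bool)
        mask[6:10, :] = True
        px[mask] = 50.0
        inside, outside = inside_outside_split(_image(px, mask))
        assert outside.integrated_density == 0.0
        assert inside.integrated_density == pytest.approx(50.0 * mask.sum())

    def test_empty_or_full_vessel_mask_raises(self):
        px = np.ones((8, 8))
        with pytest.raises(DegenerateInputError):
            inside_outside_split(
                VesselImage(px, np.zeros((8, 8), bool), pixel_area_um2=1.0)
            )
        with pytest.raises(DegenerateInputError):
            inside_outside_split(
                VesselImage(px, np.ones((8, 8), bool), pixel_area_um2=1.0)
            )

    def test_synthetic_70_30_split_recovered_within_2_points(self):
        image, truth = gen_brain_image(
            inside_amount=7.0, outside_amount=3.0, seed=11
        )
        inside, outside = inside_outside_split(
            image, floor=5.0 * truth.params["background_sigma"]
        )
        total = inside.integrated_density + outside.integrated_density
        assert 100.0 * inside.integrated_density / total == pytest.approx(70.0, abs=2.0)


class TestCalibration:
    def test_noiseless_linear_fit_is_exact(self):
        x = np.linspace(0, 30, 7)
        cal = fit_calibration(x, 50.0 * x, model="linear")
        assert cal.slope == pytest.approx(50.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.r2 == pytest.approx(1.0)

    def test_flat_densities_give_zero_slope(self):
        cal = fit_calibration([0, 10, 20, 30], [5.0] * 4, model="linear")
        assert cal.slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_amounts_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([5, 5, 5], [1, 2, 3], model="linear")

    def test_rodbard_4pl_parameter_recovery(self):
        a, b, c, d = 5.0, 2.0, 10.0, 400.0
        x = np.linspace(0.5, 40, 12)
        y = d + (a - d) / (1 + (x / c) ** b)
        cal = fit_calibration(x, y, model="rodbard")
        for key, true in zip("abcd", (a, b, c, d)):
            assert cal.params[key] == pytest.approx(true, rel=1e-4)
        assert invert_calibration(cal, predict_density(cal, 7.3)) == pytest.approx(
            7.3, rel=1e-6
        )

    def test_auto_prefers_linear_when_linear(self):
        x = np.linspace(0, 30, 7)
        assert fit_calibration(x, 50.0 * x, model="auto").model == "linear"

    def test_auto_falls_back_to_rodbard_when_curved(self):
        a, b, c, d = 5.0, 2.0, 10.0, 400.0
        x = np.linspace(0.5, 40, 12)
        y = d + (a - d) / (1 + (x / c) ** b)
        assert fit_calibration(x, y, model="auto").model == "rodbard"


class TestPercentDelivered:
    def setup_method(self):
        x = np.linspace(0, 30, 7)
        self.cal = fit_calibration(x, 50.0 * x, model="linear")

    def test_density_at_administered_amount_is_100_percent(self):
        assert percent_delivered(
            predict_density(self.cal, 12.0), self.cal, 12.0
        ) == pytest.approx(100.0)

    def test_half_density_is_50_percent(self):
        assert percent_delivered(
            predict_density(self.cal, 6.0), self.cal, 12.0
        ) == pytest.approx(50.0)

    def test_zero_administered_amount_rejected(self):
        with pytest.raises(ValueError):
            percent_delivered(100.0, self.cal, 0.0)

    def test_rodbard_density_outside_asymptotes_raises(self):
        a, b, c, d = 5.0, 2.0, 10.0, 400.0
        x = np.linspace(0.5, 40, 12)
        y = d + (a - d) / (1 + (x / c) ** b)
        cal = fit_calibration(x, y, model="rodbard")
        with pytest.raises(OutOfRangeError):
            invert_calibration(cal, 1000.0)
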