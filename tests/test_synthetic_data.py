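"""Synthetic image and cohort generators: determinism, geometry, calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from skinaging import (CohortSpec, ConfigurationError, DataError, ImageSpec,
                       ObjectRequest, PlacementError, SkinImage,
                       change_correlation, generate_cohort,
                       generate_labeled_image, plant_blob, plant_wrinkle,
                       rgb_to_lab, surround_contrast)
from skinaging.synthetic_data import solve_boundary_amplitude


def _blank_image(size=200, mm_per_px=0.1):
    lab = np.empty((size, size, 3))
    lab[...] = (59.27, 12.55, 20.39)
    from skinaging import lab_to_rgb
    return SkinImage(lab_to_rgb(lab), mm_per_px)


class TestGenerateLabeledImage:
    def test_zero_objects_pure_background(self):
        spec = ImageSpec(seed=1)
        image, planted = generate_labeled_image(spec)
        assert planted == []
        lab = rgb_to_lab(image)
        assert lab[..., 0].mean() == pytest.approx(59.27, abs=0.1)
        assert lab[..., 0].std() == pytest.approx(0.5, abs=0.1)
        assert lab[..., 1].std() < 0.05  # a*, b* noise-free by design

    def test_seed_determinism_bit_identical(self):
        spec = dict(object_requests=[ObjectRequest("spot", 2),
                                     ObjectRequest("pore", 1)], seed=77)
        img1, gt1 = generate_labeled_image(ImageSpec(**spec))
        img2, gt2 = generate_labeled_image(ImageSpec(**spec))
        assert np.array_equal(img1.rgb, img2.rgb)
        assert len(gt1) == len(gt2)
        for a, b in zip(gt1, gt2):
            assert np.array_equal(a.mask, b.mask)
            assert a.nominal_area_mm2 == b.nominal_area_mm2

    def test_different_seed_differs(self):
        img1, _ = generate_labeled_image(ImageSpec(seed=1))
        img2, _ = generate_labeled_image(ImageSpec(seed=2))
        assert not np.array_equal(img1.rgb, img2.rgb)

    def test_planted_spot_area_within_ten_percent(self):
        spec = ImageSpec(object_requests=[
            ObjectRequest("spot", 1, {"area_mm2": 6.0, "delta_e": 5.0})],
            seed=5)
        _, planted = generate_labeled_image(spec)
        measured = planted[0].mask.sum() * spec.mm_per_px ** 2
        assert measured == pytest.approx(6.0, rel=0.10)

    def test_masks_disjoint_with_separation_in_isolated_mode(self):
        spec = ImageSpec(object_requests=[ObjectRequest("pore", 4)],
                         seed=13, size_px=(300, 300))
        _, planted = generate_labeled_image(spec)
        assert len(planted) == 4
        union = np.zeros(spec.size_px, dtype=bool)
        total = 0
        for p in planted:
            assert not (union & p.mask).any()
            # >= 2 px separation: dilated masks still disjoint
            from scipy.ndimage import binary_dilation
            assert not (binary_dilation(union) & binary_dilation(p.mask)).any()
            union |= p.mask
            total += p.mask.sum()
        assert total <= union.size  # conservation: planted area <= ROI

    def test_placement_failure_reports_count(self):
        spec = ImageSpec(size_px=(170, 170),
                         object_requests=[ObjectRequest("spot", 40)],
                         seed=3, max_attempts=30)
        with pytest.raises(PlacementError) as exc:
            generate_labeled_image(spec)
        assert 0 <= exc.value.placed < 40
        assert exc.value.requested == 40


class TestPlantWrinkle:
    def test_straight_stroke_geometry(self, rng):
        image, planted = plant_wrinkle(
            _blank_image(), length_mm=10.0, width_mm=0.5,
            contrast_delta_l=8.0, curvature=0.0, rng=rng,
            center=(100.0, 100.0), orientation=0.0)
        rows = np.any(planted.mask, axis=1).sum()
        cols = np.any(planted.mask, axis=0).sum()
        # path span 100 px plus a half-width end cap at each end
        assert max(rows, cols) == pytest.approx(100, abs=6)
        area = planted.mask.sum() * 0.01
        assert area == pytest.approx(10 * 0.5 + math.pi * 0.25 ** 2,
                                     rel=0.10)
        assert planted.nominal_length_mm == 10.0

    def test_zero_contrast_leaves_image_unchanged(self, rng):
        base = _blank_image()
        image, planted = plant_wrinkle(base, 8.0, 0.4, 0.0, 0.0, rng,
                                       center=(100.0, 100.0))
        assert np.allclose(image.rgb, base.rgb, atol=1e-6)
        assert planted.mask.any()  # ground truth still recorded

    def test_out_of_bounds_names_direction(self, rng):
        with pytest.raises(DataError, match="right|left"):
            plant_wrinkle(_blank_image(), 12.0, 0.5, 8.0, 0.0, rng,
                          center=(100.0, 190.0), orientation=0.0)
        with pytest.raises(DataError, match="width_mm"):
            plant_wrinkle(_blank_image(), 1.0, 2.0, 8.0, 0.0, rng)


class TestPlantBlob:
    def test_spot_delta_e_round_trip_within_five_percent(self, rng):
        image, planted = plant_blob(_blank_image(), "spot", 6.0, 5.0, 0.0,
                                    rng, center=(100.0, 100.0))
        lab = rgb_to_lab(image)
        got = surround_contrast(lab, planted.mask, 1.0, 0.1)
        assert got == pytest.approx(5.0, rel=0.05)
        assert planted.mask.sum() * 0.01 == pytest.approx(6.0, rel=0.10)

    def test_pore_pixel_area(self, rng):
        _, planted = plant_blob(_blank_image(), "pore", 0.5, 2.5, 0.0, rng,
                                center=(100.0, 100.0))
        assert planted.mask.sum() == pytest.approx(50, rel=0.15)

    def test_zero_delta_e_invisible_but_recorded(self, rng):
        base = _blank_image()
        image, planted = plant_blob(base, "texture", 2.0, 0.0, 0.0, rng,
                                    center=(100.0, 100.0))
        assert np.allclose(image.rgb, base.rgb, atol=1e-6)
        assert planted.mask.any()

    def test_sub_resolution_refused(self, rng):
        with pytest.raises(DataError, match="sub-resolution"):
            plant_blob(_blank_image(mm_per_px=0.5), "pore", 0.5, 2.0, 0.0,
                       rng)

    def test_boundary_amplitude_raises_circularity(self):
        smooth = solve_boundary_amplitude(4 * math.pi, 5)
        assert smooth == 0.0
        amp = solve_boundary_amplitude(27.0, 5)
        assert 0.0 < amp < 0.6
        from skinaging.synthetic_data import _curve_circularity
        assert _curve_circularity(amp, 5, 1.0) == pytest.approx(27.0, rel=1e-4)


class TestCohortSpecValidation:
    def test_defaults_valid(self):
        CohortSpec().validate()

    @pytest.mark.parametrize("kwargs,match", [
        (dict(recovery_fraction={"2M": 0.5, "8M": 0.4, "12M": 0.8}),
         "nondecreasing"),
        (dict(response_correlation=1.0), "response_correlation"),
        (dict(parameters={"hydration": (50.0, 0.0, 45.0, 1.0)}), "positive"),
        (dict(recovery_fraction={"2M": 0.5, "8M": 0.6, "12M": 1.2}),
         r"\[0, 1\]"),
    ])
    def test_invalid_specs_rejected(self, kwargs, match):
        with pytest.raises(ConfigurationError, match=match):
            CohortSpec(**kwargs).validate()

    def test_unachievable_correlation_names_parameter(self):
        spec = CohortSpec(response_correlation=-0.95)
        with pytest.raises(ConfigurationError, match="tewl"):
            generate_cohort(spec)


class TestGenerateCohort:
    def test_seed_determinism(self):
        a = generate_cohort(CohortSpec(seed=4))
        b = generate_cohort(CohortSpec(seed=4))
        pd.testing.assert_frame_equal(a, b)

    def test_tidy_shape_and_uniqueness(self):
        spec = CohortSpec(n_subjects=10, seed=0)
        df = generate_cohort(spec)
        assert set(df.columns) == {"subject_id", "timepoint", "parameter",
                                   "value"}
        assert len(df) == 10 * 5 * len(spec.parameters)
        assert not df.duplicated(["subject_id", "timepoint",
                                  "parameter"]).any()

    def test_no_treatment_null_means_stay_at_pretreat(self):
        spec = CohortSpec(n_subjects=4000,
                          recovery_fraction={"2M": 0.0, "8M": 0.0,
                                             "12M": 0.0}, seed=6)
        df = generate_cohort(spec)
        wide = df[df.parameter == "hydration"].pivot(
            index="subject_id", columns="timepoint", values="value")
        # E[12M] = E[0M]; at n = 4000 the sample means agree within 4 SE
        se = wide["0M"].std() / math.sqrt(len(wide))
        assert abs(wide["12M"].mean() - wide["0M"].mean()) < 4 * se + 0.3

    def test_full_recovery_noise_free_equals_baseline(self):
        spec = CohortSpec(n_subjects=50, seed=8,
                          recovery_fraction={"2M": 1.0, "8M": 1.0,
                                             "12M": 1.0},
                          hydration_response_sd_frac=0.0,
                          outcome_noise_frac=0.0)
        df = generate_cohort(spec)
        wide = df[df.parameter == "wrinkles"].pivot(
            index="subject_id", columns="timepoint", values="value")
        assert np.allclose(wide["12M"], wide["1999"])

    def test_response_correlation_recovered_at_large_n(self):
        df = generate_cohort(CohortSpec(n_subjects=5000, seed=7))
        res = change_correlation(df, "hydration", "tewl", "0M", "12M")
        assert res.r == pytest.approx(-0.32, abs=0.04)

    def test_zero_response_correlation_null(self):
        df = generate_cohort(CohortSpec(n_subjects=1000,
                                        response_correlation=0.0, seed=3))
        res = change_correlation(df, "hydration", "tewl", "0M", "12M")
        assert abs(res.r) < 0.1

    def test_table_calibrated_means_one_seed(self):
        from skinaging import REFERENCE_COHORT_CALIBRATION
        df = generate_cohort(CohortSpec(seed=123))
        m99, s99, m0, s0 = REFERENCE_COHORT_CALIBRATION["hydration"]
        v99 = df[(df.parameter == "hydration")
                 & (df.timepoint == "1999")]["value"]
        assert abs(v99.mean() - m99) <= 3 * s99 / math.sqrt(86)
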