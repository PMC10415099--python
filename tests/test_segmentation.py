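import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from adcseg.segmentation import (
    SegmentationConfig,
    adc_gate,
    delineate,
    gaussian_smooth,
    mirror_subtract,
    parenchyma_mask,
    primary_mask,
    ratio_image,
    slice_normalize,
    trace_percentile_cleanup,
)
from adcseg.phantom import PhantomSpec, generate_case
from adcseg.volume_io import GridMismatchError
from conftest import adc_volume, full_mask, mask, volume

CFG = SegmentationConfig()


class TestRatioImage:
    def test_direct_division(self):
        trace = volume(np.full((4, 4, 4), 100.0))
        adc = adc_volume(np.full((4, 4, 4), 200.0))
        out = ratio_image(trace, adc, full_mask((4, 4, 4)))
        np.testing.assert_allclose(out.data, 0.5)

    def test_zero_adc_guarded(self):
        trace = volume(np.full((3, 3, 3), 100.0))
        adc_data = np.full((3, 3, 3), 200.0)
        adc_data[1, 1, 1] = 0.0
        out = ratio_image(trace, adc_volume(adc_data), full_mask((3, 3, 3)))
        assert out.data[1, 1, 1] == 0.0
        assert out.data[0, 0, 0] == 0.5

    def test_zero_outside_brain(self):
        trace = volume(np.full((3, 3, 3), 100.0))
        adc = adc_volume(np.full((3, 3, 3), 200.0))
        brain = np.zeros((3, 3, 3), dtype=bool)
        brain[1, 1, 1] = True
        out = ratio_image(trace, adc, mask(brain))
        assert out.data[1, 1, 1] == 0.5
        assert out.data[0, 0, 0] == 0.0

    def test_lesion_contrast_amplified(self):
        # high trace / low ADC (lesion) beats low trace / high ADC (parenchyma)
        assert (606.0 / 500.0) > (427.0 / 850.0)
        trace = volume(np.array([[[606.0, 427.0]]]))
        adc = adc_volume(np.array([[[500.0, 850.0]]]))
        out = ratio_image(trace, adc, full_mask((1, 1, 2)))
        assert out.data[0, 0, 0] > out.data[0, 0, 1]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            ratio_image(
                volume(np.zeros((3, 3, 3))),
                adc_volume(np.zeros((4, 3, 3))),
                full_mask((3, 3, 3)),
            )


class TestSliceNormalize:
    def test_constant_slice_becomes_one(self):
        img = volume(np.full((4, 4, 2), 7.0))
        out = slice_normalize(img, full_mask((4, 4, 2)), slice_axis=2)
        np.testing.assert_allclose(out.data, 1.0)

    def test_two_value_slice(self):
        data = np.zeros((2, 1, 1))
        data[0, 0, 0], data[1, 0, 0] = 1.0, 3.0
        out = slice_normalize(volume(data), full_mask((2, 1, 1)), slice_axis=2)
        np.testing.assert_allclose(out.data[:, 0, 0], [0.5, 1.5])

    def test_empty_slice_left_zero(self):
        data = np.ones((3, 3, 2))
        brain = np.zeros((3, 3, 2), dtype=bool)
        brain[:, :, 0] = True
        out = slice_normalize(volume(data), mask(brain), slice_axis=2)
        np.testing.assert_allclose(out.data[:, :, 0], 1.0)
        np.testing.assert_allclose(out.data[:, :, 1], 0.0)

    def test_mean_uses_brain_voxels_only(self):
        data = np.zeros((2, 2, 1))
        data[0, 0, 0] = 4.0
        data[1, 1, 0] = 100.0  # outside brain: must not affect the mean
        brain = np.zeros((2, 2, 1), dtype=bool)
        brain[0, :, 0] = True
        out = slice_normalize(volume(data), mask(brain), slice_axis=2)
        np.testing.assert_allclose(out.data[0, 0, 0], 2.0)  # mean of {4, 0} = 2
        assert out.data[1, 1, 0] == 0.0


class TestGaussianSmooth:
    def test_constant_preserved_in_interior(self):
        # kernel radius at 6 sigma is 13 voxels: the centre of a 31-voxel
        # cube is beyond the boundary-effect margin
        img = volume(np.full((31, 31, 31), 3.0))
        out = gaussian_smooth(img, fwhm_vox=5.0)
        np.testing.assert_allclose(out.data[15, 15, 15], 3.0, rtol=1e-9)

    def test_impulse_centre_matches_discrete_kernel(self):
        # independent construction of the sampled, normalized Gaussian kernel
        fwhm = 5.0
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        radius = int(6.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        w = np.exp(-(x**2) / (2.0 * sigma**2))
        w /= w.sum()
        data = np.zeros((31, 31, 31))
        data[15, 15, 15] = 1.0
        out = gaussian_smooth(volume(data), fwhm)
        np.testing.assert_allclose(out.data[15, 15, 15], w[radius] ** 3, rtol=1e-12)
        assert out.data.sum() <= 1.0 + 1e-9

    def test_semigroup_property(self):
        rng = np.random.default_rng(0)
        img = volume(rng.normal(size=(24, 24, 24)))
        twice = gaussian_smooth(gaussian_smooth(img, 3.0), 3.0)
        once = gaussian_smooth(img, 3.0 * np.sqrt(2.0))
        interior = (slice(8, 16),) * 3
        np.testing.assert_allclose(twice.data[interior], once.data[interior], atol=1e-6)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            gaussian_smooth(volume(np.zeros((4, 4, 4))), 0.0)


class TestMirrorSubtract:
    def test_symmetric_input_cancels(self):
        rng = np.random.default_rng(1)
        half = rng.random((3, 6, 6))
        data = np.concatenate([half, half[::-1]], axis=0)
        out = mirror_subtract(volume(data), mirror_axis=0)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_hand_subtraction_with_clipping(self):
        data = np.zeros((4, 1, 1))
        data[0, 0, 0] = 2.0
        data[3, 0, 0] = 0.5  # mirror voxel of index 0 along a length-4 axis
        out = mirror_subtract(volume(data), mirror_axis=0)
        assert out.data[0, 0, 0] == 1.5
        assert out.data[3, 0, 0] == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(arrays(np.float64, (4, 4, 4), elements=st.floats(-10, 10)))
    def test_output_nonnegative_and_one_sided(self, data):
        out = mirror_subtract(volume(data), mirror_axis=0).data
        assert (out >= 0).all()
        # a voxel and its mirror cannot both keep positive residuals
        assert not ((out > 0) & (np.flip(out, axis=0) > 0)).any()

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(arrays(np.float64, (4, 4, 4), elements=st.floats(-5, 5)))
    def test_second_application_idempotent_iff_one_sided(self, data):
        once = mirror_subtract(volume(data), 0)
        twice = mirror_subtract(once, 0)
        if (np.flip(once.data, axis=0) <= once.data).all():
            np.testing.assert_array_equal(twice.data, once.data)


class TestPrimaryMask:
    def test_zero_image_gives_empty_mask(self):
        out = primary_mask(volume(np.zeros((5, 5, 5))), full_mask((5, 5, 5)), CFG)
        assert out.voxel_count == 0

    def test_single_voxel_dilates_to_face_neighbours(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1.0
        out = primary_mask(volume(data), full_mask((5, 5, 5)), CFG)
        assert out.voxel_count == 7
        expected = {(2, 2, 2), (1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1), (2, 2, 3)}
        assert set(zip(*np.nonzero(out.data))) == expected

    def test_threshold_is_inclusive(self):
        data = np.zeros((1, 1, 3))
        data[0, 0] = [0.74, 0.75, 0.76]
        cfg = SegmentationConfig(dilation_iterations=0)
        out = primary_mask(volume(data), full_mask((1, 1, 3)), cfg)
        np.testing.assert_array_equal(out.data[0, 0], [False, True, True])

    def test_dilation_restricted_to_brain(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1.0
        brain = np.zeros((5, 5, 5), dtype=bool)
        brain[2, 2, :] = True
        out = primary_mask(volume(data), mask(brain), CFG)
        assert set(zip(*np.nonzero(out.data))) == {(2, 2, 1), (2, 2, 2), (2, 2, 3)}


class TestAdcGate:
    def test_band_membership_inclusive(self):
        vals = np.array([150.0, 200.0, 450.0, 620.0, 700.0])
        data = np.zeros((1, 1, 5))
        data[0, 0] = vals
        out = adc_gate(full_mask((1, 1, 5)), adc_volume(data), CFG)
        np.testing.assert_array_equal(out.data[0, 0], [False, True, True, True, False])

    def test_empty_mask_stays_empty(self):
        out = adc_gate(mask(np.zeros((3, 3, 3))), adc_volume(np.full((3, 3, 3), 400.0)), CFG)
        assert out.voxel_count == 0

    def test_unbounded_band_is_identity(self):
        cfg = SegmentationConfig(adc_lower=0.0, adc_upper=np.inf)
        rng = np.random.default_rng(2)
        m = mask(rng.random((4, 4, 4)) > 0.5)
        out = adc_gate(m, adc_volume(rng.random((4, 4, 4)) * 1000), cfg)
        np.testing.assert_array_equal(out.data, m.data)


class TestTracePercentileCleanup:
    def test_independent_percentile_computation(self):
        # parenchyma trace values 1..100: the linear-interpolation 95th
        # percentile is 95.05, so trace 90 is removed and 99 kept
        paren_vals = np.arange(1.0, 101.0)
        data = np.zeros((2, 100, 1))
        data[0, :, 0] = paren_vals
        data[1, 0, 0], data[1, 1, 0] = 90.0, 99.0
        paren = np.zeros((2, 100, 1), dtype=bool)
        paren[0, :, 0] = True
        candidates = np.zeros((2, 100, 1), dtype=bool)
        candidates[1, :2, 0] = True
        assert np.percentile(paren_vals, 95) == pytest.approx(95.05)
        out = trace_percentile_cleanup(mask(candidates), volume(data), mask(paren), CFG)
        assert not out.data[1, 0, 0]
        assert out.data[1, 1, 0]

    def test_all_above_cutoff_unchanged(self):
        trace = volume(np.full((3, 3, 3), 50.0))
        m = full_mask((3, 3, 3))
        out = trace_percentile_cleanup(m, trace, m, CFG)
        np.testing.assert_array_equal(out.data, m.data)

    def test_percentile_zero_keeps_positive_traces(self):
        cfg = SegmentationConfig(trace_percentile=0.0)
        rng = np.random.default_rng(3)
        trace = volume(rng.random((4, 4, 4)) + 0.1)
        m = full_mask((4, 4, 4))
        out = trace_percentile_cleanup(m, trace, m, cfg)
        np.testing.assert_array_equal(out.data, m.data)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            trace_percentile_cleanup(
                full_mask((3, 3, 3)), volume(np.ones((3, 3, 3))), mask(np.zeros((3, 3, 3))), CFG
            )


class TestParenchymaMask:
    def test_csf_excluded_in_noise_free_phantom(self, noisefree_case):
        out = parenchyma_mask(noisefree_case.adc, noisefree_case.brain_mask, CFG)
        csf = noisefree_case.brain_mask.data & (noisefree_case.adc.data >= 2000.0)
        assert csf.any()
        assert not (out.data & csf).any()
        assert (out.data | csf).sum() == noisefree_case.brain_mask.voxel_count

    def test_infinite_cutoff_returns_brain(self, small_case):
        cfg = SegmentationConfig(csf_adc_cutoff=np.inf)
        out = parenchyma_mask(small_case.adc, small_case.brain_mask, cfg)
        np.testing.assert_array_equal(out.data, small_case.brain_mask.data)

    def test_zero_cutoff_warns_and_is_empty(self, small_case):
        cfg = SegmentationConfig(csf_adc_cutoff=0.0)
        with pytest.warns(UserWarning):
            out = parenchyma_mask(small_case.adc, small_case.brain_mask, cfg)
        assert out.voxel_count == 0


class TestDelineate:
    def test_final_mask_obeys_band_brain_and_primary(self, small_case):
        res = delineate(small_case.b0, small_case.trace, small_case.adc,
                        small_case.brain_mask, CFG)
        final = res.lesion_mask.data
        assert not (final & ~res.primary_mask.data).any()
        assert not (final & ~small_case.brain_mask.data).any()
        adc_in = small_case.adc.data[final]
        assert final.sum() > 0
        assert adc_in.min() >= CFG.adc_lower and adc_in.max() <= CFG.adc_upper

    def test_stage_log_monotone_after_gate(self, small_case):
        res = delineate(small_case.b0, small_case.trace, small_case.adc,
                        small_case.brain_mask, CFG)
        counts = dict(res.stage_log)
        assert counts["adc_gate"] <= counts["primary_mask"]
        assert counts["trace_cleanup"] <= counts["adc_gate"]

    def test_symmetric_phantom_yields_empty_mask(self):
        spec = PhantomSpec(grid_shape=(32, 38, 32), lesion_radii_vox=None,
                           noise_sd=0.0, seed=11)
        case = generate_case(spec)
        res = delineate(case.b0, case.trace, case.adc, case.brain_mask, CFG)
        assert res.lesion_mask.voxel_count == 0

    def test_high_adc_lesion_suppressed_by_gate(self):
        # lesion ADC above the 620 band: trace-hyperintense but not delineated
        spec = PhantomSpec(grid_shape=(32, 38, 32), lesion_radii_vox=(3.0, 3.4, 3.0),
                           lesion_adc_mean=700.0, lesion_adc_sd=10.0, seed=13)
        case = generate_case(spec)
        res = delineate(case.b0, case.trace, case.adc, case.brain_mask, CFG)
        assert res.lesion_mask.voxel_count < 0.1 * case.truth_lesion.voxel_count

    def test_deterministic(self, small_case):
        a = delineate(small_case.b0, small_case.trace, small_case.adc,
                      small_case.brain_mask, CFG)
        b = delineate(small_case.b0, small_case.trace, small_case.adc,
                      small_case.brain_mask, CFG)
        np.testing.assert_array_equal(a.lesion_mask.data, b.lesion_mask.data)
        assert a.stage_log == b.stage_log
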