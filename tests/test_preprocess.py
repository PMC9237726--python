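import numpy as np
import pytest

import specmap as sm
from specmap.errors import (
    DegenerateSpectrumError,
    MaskError,
    ParameterError,
    SpacingError,
    WindowError,
)

from conftest import gaussian


class TestDetectEmpty:
    def test_recovers_seeded_holes_exactly(self, default_scene, rendered_scene):
        mask = sm.detect_empty(rendered_scene)
        assert np.array_equal(mask.excluded_indices, default_scene.holes)
        assert all(mask.reason[i] == "empty" for i in mask.excluded_indices)

    def test_oracle_mean_and_compare_loop(self, rendered_scene):
        params = sm.PreprocessParams()
        mask = sm.detect_empty(rendered_scene, params)
        lo, hi = params.empty_window
        for i in range(rendered_scene.n_pixels):
            sel = (rendered_scene.axis >= lo) & (rendered_scene.axis <= hi)
            expect = rendered_scene.absorbance[i, sel].mean() >= params.empty_threshold
            assert mask.keep[i] == expect

    def test_threshold_zero_keeps_nonnegative_fixture(self):
        axis = np.arange(1500.0, 1801.0)
        m = sm.SpectralMap(np.vstack([gaussian(axis, 1654, 10), np.zeros(axis.size)]), axis)
        mask = sm.detect_empty(m, sm.PreprocessParams(empty_threshold=0.0))
        assert mask.keep.all()

    def test_all_zero_map_all_excluded(self):
        axis = np.arange(1500.0, 1801.0)
        m = sm.SpectralMap(np.zeros((4, axis.size)), axis)
        mask = sm.detect_empty(m)
        assert not mask.keep.any()
        assert all(r == "empty" for r in mask.reason)

    def test_window_outside_axis_raises(self):
        m = sm.SpectralMap([[1.0, 1.0]], [1000.0, 1010.0])
        with pytest.raises(WindowError):
            sm.detect_empty(m)


class TestDetectScatter:
    def test_slope_criterion_with_closed_form_oracle(self):
        axis = np.arange(1000.0, 3001.0, 2.0)
        base = gaussian(axis, 1654, 12)
        sloped = base + 2e-3 * (axis - axis[0])
        m = sm.SpectralMap(np.vstack([base, sloped]), axis)
        params = sm.PreprocessParams(scatter_slope_threshold=1e-3)
        # oracle: closed-form least-squares slope over the silent window
        sel = (axis >= 1800) & (axis <= 2600)
        w = axis[sel] - axis[sel].mean()
        slope = w @ (sloped[sel] - sloped[sel].mean()) / (w @ w)
        assert abs(slope) > 1e-3
        mask = sm.detect_scatter(m, params)
        assert list(mask.keep) == [True, False]
        assert mask.reason[1] == "scatter"

    def test_recovers_seeded_scatter_pixels_exactly(self, default_scene, rendered_scene):
        mask = sm.detect_scatter(rendered_scene)
        assert np.array_equal(mask.excluded_indices, default_scene.scatter_pixels)

    def test_flat_spectrum_kept(self):
        axis = np.arange(1000.0, 3001.0, 2.0)
        m = sm.SpectralMap(np.full((1, axis.size), 0.3), axis)
        assert sm.detect_scatter(m).keep.all()

    def test_negative_fraction_criterion(self):
        axis = np.arange(1000.0, 3001.0, 2.0)
        m = sm.SpectralMap(np.full((1, axis.size), -0.1), axis)
        params = sm.PreprocessParams(scatter_negative_fraction_threshold=0.5)
        mask = sm.detect_scatter(m, params)
        assert not mask.keep[0] and mask.reason[0] == "scatter"


class TestExcludeCO2:
    def test_removes_expected_point_count(self):
        axis = np.arange(1000.0, 3001.0, 2.0)
        m = sm.SpectralMap(np.ones((2, axis.size)), axis)
        out = sm.exclude_co2(m)
        # oracle: count of axis points in the closed interval
        n_inside = int(((axis >= 2300) & (axis <= 2400)).sum())
        assert n_inside == 51
        assert out.n_wavenumbers == axis.size - n_inside
        assert not ((out.axis >= 2300) & (out.axis <= 2400)).any()

    def test_disjoint_window_is_identity(self):
        axis = np.arange(1000.0, 2001.0, 2.0)
        m = sm.SpectralMap(np.ones((1, axis.size)), axis)
        out = sm.exclude_co2(m, sm.PreprocessParams(co2_window=(9000.0, 9100.0)))
        assert np.array_equal(out.axis, m.axis)
        assert np.array_equal(out.absorbance, m.absorbance)

    def test_idempotent(self):
        axis = np.arange(1000.0, 3001.0, 2.0)
        m = sm.SpectralMap(np.ones((1, axis.size)), axis)
        once = sm.exclude_co2(m)
        twice = sm.exclude_co2(once)
        assert np.array_equal(once.axis, twice.axis)


class TestVectorNormalize:
    def test_three_four_five(self):
        m = sm.SpectralMap([[3.0, 4.0]], [1000.0, 1010.0])
        out = sm.vector_normalize(m)
        np.testing.assert_allclose(out.absorbance, [[0.6, 0.8]], atol=1e-15)

    def test_unit_norms_random_matrix(self):
        rng = np.random.default_rng(7)
        m = sm.SpectralMap(rng.uniform(0.01, 1, (10, 50)), np.arange(1000.0, 1500.0, 10.0))
        out = sm.vector_normalize(m)
        np.testing.assert_allclose(np.linalg.norm(out.absorbance, axis=1), 1.0, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        m = sm.SpectralMap(rng.uniform(0.01, 1, (5, 20)), np.arange(1000.0, 1200.0, 10.0))
        once = sm.vector_normalize(m)
        twice = sm.vector_normalize(once)
        np.testing.assert_allclose(once.absorbance, twice.absorbance, atol=1e-12)

    def test_scale_invariant(self):
        rng = np.random.default_rng(9)
        data = rng.uniform(0.01, 1, (5, 20))
        axis = np.arange(1000.0, 1200.0, 10.0)
        a = sm.vector_normalize(sm.SpectralMap(data, axis))
        b = sm.vector_normalize(sm.SpectralMap(data * 37.5, axis))
        np.testing.assert_allclose(a.absorbance, b.absorbance, atol=1e-12)

    def test_zero_row_names_pixel(self):
        m = sm.SpectralMap([[1.0, 1.0], [0.0, 0.0]], [1000.0, 1010.0])
        with pytest.raises(DegenerateSpectrumError, match="pixel 1"):
            sm.vector_normalize(m)


class TestSecondDerivative:
    def test_affine_rows_annihilated(self):
        axis = np.arange(1000.0, 1101.0)
        data = np.vstack([2.0 + 0.5 * axis, -3.0 + 1e-2 * axis, np.full(axis.size, 7.0)])
        out = sm.second_derivative(sm.SpectralMap(data, axis))
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-9)

    def test_quadratic_gives_constant_two(self):
        axis = np.arange(1.0, 101.0)  # unit spacing
        data = (axis ** 2)[None, :]
        out = sm.second_derivative(sm.SpectralMap(data, axis))
        interior = out.absorbance[0, 4:-4]
        np.testing.assert_allclose(interior, 2.0, atol=1e-8)

    def test_baseline_offset_invariance(self):
        axis = np.arange(1000.0, 1101.0)
        rng = np.random.default_rng(1)
        data = rng.normal(size=(3, axis.size))
        out1 = sm.second_derivative(sm.SpectralMap(data, axis))
        out2 = sm.second_derivative(sm.SpectralMap(data + 123.456, axis))
        np.testing.assert_allclose(out1.absorbance, out2.absorbance, atol=1e-9)

    def test_spacing_scaling(self):
        # d2/dw2 of w^2 is 2 regardless of spacing, so values scale by h^-2
        axis = np.arange(1000.0, 1200.0, 2.0)
        out = sm.second_derivative(sm.SpectralMap((axis ** 2)[None, :], axis))
        np.testing.assert_allclose(out.absorbance[0, 4:-4], 2.0, atol=1e-8)

    def test_non_uniform_axis_rejected(self):
        axis = np.cumsum(np.abs(np.random.default_rng(2).normal(2, 0.5, 50))) + 1000
        m = sm.SpectralMap(np.ones((1, 50)), axis)
        with pytest.raises(SpacingError):
            sm.second_derivative(m)

    def test_gap_from_co2_excision_handled_segmentwise(self):
        axis = np.arange(1000.0, 3001.0, 2.0)
        m = sm.SpectralMap((2.0 + 0.1 * axis)[None, :], axis)
        gapped = sm.exclude_co2(m)
        out = sm.second_derivative(gapped)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-9)

    def test_invalid_window_parameters(self):
        with pytest.raises(ParameterError):
            sm.PreprocessParams(sg_window_pts=4)
        with pytest.raises(ParameterError):
            sm.PreprocessParams(sg_polyorder=9, sg_window_pts=9)


class TestApplyMaskAndCompose:
    def test_all_true_identity(self, simple_map):
        out = sm.apply_mask(simple_map, sm.QCMask.all_true(4))
        assert np.array_equal(out.absorbance, simple_map.absorbance)

    def test_all_false_gives_zero_pixel_map(self, simple_map):
        mask = sm.QCMask(np.zeros(4, bool), np.array(["manual"] * 4, dtype=object))
        out = sm.apply_mask(simple_map, mask)
        assert out.n_pixels == 0

    def test_row_subset_order_preserved(self):
        axis = np.array([1000.0, 1010.0])
        m = sm.SpectralMap(np.arange(10.0).reshape(5, 2), axis)
        mask = sm.QCMask.from_excluded(5, [1, 3], "manual")
        out = sm.apply_mask(m, mask)
        assert np.array_equal(out.absorbance, m.absorbance[[0, 2, 4]])

    def test_length_mismatch(self, simple_map):
        with pytest.raises(MaskError):
            sm.apply_mask(simple_map, sm.QCMask.all_true(3))

    def test_composition_order_independent_keep(self, rendered_scene):
        e = sm.detect_empty(rendered_scene)
        s = sm.detect_scatter(rendered_scene)
        assert np.array_equal((e & s).keep, (s & e).keep)

    def test_first_mask_reason_wins(self):
        a = sm.QCMask.from_excluded(3, [1], "empty")
        b = sm.QCMask.from_excluded(3, [1, 2], "scatter")
        ab = a & b
        assert ab.reason[1] == "empty" and ab.reason[2] == "scatter"
        ba = b & a
        assert ba.reason[1] == "scatter"

    def test_detectors_do_not_change_data(self, rendered_scene):
        before = rendered_scene.absorbance.copy()
        sm.detect_empty(rendered_scene)
        sm.detect_scatter(rendered_scene)
        assert np.array_equal(rendered_scene.absorbance, before)
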