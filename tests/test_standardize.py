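"""Template geometry and the standardized-map resampling chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertemap import (FieldSpec, TemplateGeometry, build_standardized_maps,
                      map_transverse_slice, resample_masked_run)
from vertemap.errors import EmptyMaskError, EmptyRunError, GeometryError

from conftest import make_roi


class TestResampleMaskedRun:
    def test_closed_form_examples(self):
        np.testing.assert_allclose(resample_masked_run([10, 20, 30], 5),
                                   [10, 15, 20, 25, 30])
        np.testing.assert_allclose(resample_masked_run([7] * 9, 13),
                                   np.full(13, 7.0))
        np.testing.assert_allclose(resample_masked_run([0, 100], 41),
                                   np.arange(41) * 2.5)

    def test_single_sample_broadcasts(self):
        np.testing.assert_array_equal(resample_masked_run([42.0], 6),
                                      np.full(6, 42.0))

    def test_empty_run_raises(self):
        with pytest.raises(EmptyRunError):
            resample_masked_run([], 5)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        values=st.lists(st.floats(0, 100, allow_nan=False), min_size=1,
                        max_size=30),
        n_out=st.integers(2, 64),
    )
    def test_endpoints_and_convexity(self, values, n_out):
        """Output stays within the input range and pins both endpoints."""
        out = resample_masked_run(values, n_out)
        assert out.shape == (n_out,)
        assert out[0] == pytest.approx(values[0])
        assert out[-1] == pytest.approx(values[-1])
        assert out.min() >= min(values) - 1e-9
        assert out.max() <= max(values) + 1e-9


class TestTemplateGeometry:
    def test_default_grid_dimensions(self):
        g = TemplateGeometry()
        assert (g.n_rows, g.n_cols) == (33, 41)
        assert g.ellipse_mask.shape == (33, 41)

    def test_ellipse_mask_is_centered_ellipse(self):
        g = TemplateGeometry()
        i = np.arange(-g.n_major, g.n_major + 1)
        j = np.arange(-g.n_minor, g.n_minor + 1)
        jj, ii = np.meshgrid(j, i, indexing="ij")
        expected = (ii / g.n_major) ** 2 + (jj / g.n_minor) ** 2 <= 1 + 1e-12
        np.testing.assert_array_equal(g.ellipse_mask, expected)
        # mirror symmetry in both directions, odd chord widths
        np.testing.assert_array_equal(g.ellipse_mask, g.ellipse_mask[::-1])
        np.testing.assert_array_equal(g.ellipse_mask, g.ellipse_mask[:, ::-1])
        widths = g.ellipse_mask.sum(axis=1)
        assert np.all(widths[widths > 0] % 2 == 1)

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError):
            TemplateGeometry(n_major=1)


class TestTransverseMapping:
    def test_uniform_slice_maps_to_uniform_ellipse(self):
        g = TemplateGeometry()
        mask = np.zeros((21, 27), dtype=bool)
        yy, xx = np.mgrid[:21, :27]
        mask[((yy - 10) / 8.0) ** 2 + ((xx - 13) / 11.0) ** 2 <= 1] = True
        out = map_transverse_slice(np.where(mask, 40.0, 0.0), mask, g)
        assert np.all(out[g.ellipse_mask] == 40.0)
        assert np.all(np.isnan(out[~g.ellipse_mask]))

    def test_radially_symmetric_field_gives_mirror_symmetric_map(self):
        g = TemplateGeometry()
        yy, xx = np.mgrid[:41, :41]
        r2 = ((yy - 20) / 15.0) ** 2 + ((xx - 20) / 15.0) ** 2
        mask = r2 <= 1
        field = 30.0 + 10.0 * r2
        out = map_transverse_slice(np.where(mask, field, 0.0), mask, g)
        ok = g.ellipse_mask
        for mirrored in (out[::-1], out[:, ::-1]):
            diff = np.abs(out - mirrored)[ok & ok[::-1]]
            assert np.nanmax(diff) <= 0.5

    def test_shape_independence_of_two_ellipse_masks(self):
        """Same normalized field through different ellipse sizes -> same map."""
        g = TemplateGeometry()
        maps = []
        for (a, b) in [(15.0, 10.0), (21.0, 14.0)]:
            n = int(2 * a) + 5
            m = int(2 * b) + 5
            yy, xx = np.mgrid[:m, :n]
            v = (yy - (m - 1) / 2) / b
            u = (xx - (n - 1) / 2) / a
            mask = u**2 + v**2 <= 1
            field = 40.0 + 8.0 * u - 6.0 * v + 4.0 * (u**2 + v**2)
            maps.append(map_transverse_slice(np.where(mask, field, 0.0),
                                             mask, g))
        diff = np.abs(maps[0] - maps[1])[g.ellipse_mask]
        assert np.nanmax(diff) <= 2.0

    def test_empty_slice_raises(self):
        g = TemplateGeometry()
        with pytest.raises(EmptyMaskError):
            map_transverse_slice(np.zeros((5, 5)), np.zeros((5, 5), bool), g)


class TestBuildMaps:
    def test_uniform_phantom_gives_uniform_maps(self, uniform_roi):
        maps = build_standardized_maps(uniform_roi)
        assert maps.transverse.shape == (33, 41)
        assert maps.sagittal.shape == (20, 33)
        assert maps.coronal.shape == (20, 41)
        for arr, ok in maps.planes().values():
            assert np.all(arr[ok] == 40.0)

    def test_longitudinal_gradient_produces_linear_ramp(self):
        """Coronal rows follow the analytic w-ramp of the phantom field."""
        g_w = 10.0
        roi, spec = make_roi(field=FieldSpec(40.0, (0.0, 0.0, g_w)),
                             height=30.0, spacing=(1.2, 1.2, 0.8))
        maps = build_standardized_maps(roi)
        row_means = maps.coronal.mean(axis=1)
        # expected w-extent: slice centers of the rasterized mask
        zs = np.flatnonzero(roi.mask.any(axis=(1, 2)))
        z_mm = zs * roi.spacing_mm[2]
        w = (z_mm - z_mm.mean()) / (spec.vertebrae[0].height_mm / 2)
        expected_span = g_w * (w[-1] - w[0])
        span = row_means[-1] - row_means[0]
        assert span == pytest.approx(expected_span, abs=0.5)
        # and the ramp is linear
        resid = row_means - np.polyval(
            np.polyfit(np.arange(20), row_means, 1), np.arange(20))
        assert np.max(np.abs(resid)) <= 0.2

    def test_map_extrema_never_exceed_volumetric_extrema(self):
        from vertemap import map_stats, volumetric_stats

        roi, _ = make_roi(field=FieldSpec(40.0, (8.0, -6.0, 5.0), 4.0),
                          noise=6.0, seed=3)
        vs = volumetric_stats(roi)
        ms = map_stats(build_standardized_maps(roi))
        assert ms.min >= vs.min - 1e-9
        assert ms.max <= vs.max + 1e-9

    def test_scale_invariance_under_inplane_upsampling(self):
        f = FieldSpec(40.0, (8.0, -6.0, 5.0), 4.0)
        coarse, _ = make_roi(field=f, spacing=(1.2, 1.2, 1.5))
        fine, _ = make_roi(field=f, spacing=(0.6, 0.6, 1.5))
        a = build_standardized_maps(coarse)
        b = build_standardized_maps(fine)
        for plane in ("transverse", "sagittal", "coronal"):
            diff = np.abs(getattr(a, plane) - getattr(b, plane))
            assert np.nanmax(diff) <= 1.0

    def test_thin_mask_rejected(self):
        roi, _ = make_roi(height=2.0, spacing=(1.2, 1.2, 3.0))
        with pytest.raises(GeometryError):
            build_standardized_maps(roi)

    def test_correction_records_angle(self):
        roi, _ = make_roi(b=12.0, exponent=2.5, tilt=10.0,
                          spacing=(1.2, 1.2, 0.8))
        maps = build_standardized_maps(roi, correct_inclination=True)
        assert maps.inclination_corrected
        assert maps.inclination_deg == pytest.approx(10.0, abs=1.5)

    def test_valid_pixels_stay_in_pdff_range(self):
        roi, _ = make_roi(field=FieldSpec(50.0, (10.0, 10.0, 10.0), 5.0),
                          noise=8.0, seed=1)
        maps = build_standardized_maps(roi)
        vals = maps.valid_values()
        assert vals.min() >= 0.0 and vals.max() <= 100.0
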