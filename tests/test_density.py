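import numpy as np
import pytest

from conemetrics import (
    ConeField,
    ScaleInfo,
    compute_density_matrix,
    crop_density_matrix,
    density_at,
    tessellate,
    to_angular,
)
from conemetrics.synthetic_data import MosaicParams, generate_mosaic

from conftest import hex_field


class TestTessellate:
    def test_hex_interior_cell_is_regular_hexagon(self):
        f, s = hex_field(density_per_mm2=187_800.0, roi_um=40.0)
        tess = tessellate(f)
        center = np.array([20.0, 20.0]) / f.um_per_pixel
        i = int(np.argmin(np.linalg.norm(f.points - center, axis=1)))
        assert tess.finite[i] and tess.bounded[i]
        assert tess.areas_um2[i] == pytest.approx(np.sqrt(3) / 2 * s**2, rel=1e-9)
        assert len(tess.regions[i]) == 6

    def test_four_corner_points_all_unbounded(self):
        f = ConeField(points=np.array([[10., 10.], [10., 90.], [90., 10.], [90., 90.]]),
                      um_per_pixel=1.0, roi_side_um=100.0)
        tess = tessellate(f)
        assert not tess.finite.any()
        assert not tess.bounded.any()

    def test_bounded_cell_areas_do_not_exceed_roi(self, uniform_mosaic):
        tess = tessellate(uniform_mosaic)
        total = np.nansum(np.where(tess.bounded, tess.areas_um2, np.nan))
        assert total <= uniform_mosaic.roi_side_um**2

    def test_collinear_input_rejected(self):
        f = ConeField(points=np.column_stack([np.arange(5.0), np.arange(5.0)]),
                      um_per_pixel=1.0, roi_side_um=100.0)
        with pytest.raises(ValueError, match="degenerate"):
            tessellate(f)

    def test_too_few_points_rejected(self):
        f = ConeField(points=np.array([[1., 1.], [2., 5.], [7., 2.]]),
                      um_per_pixel=1.0, roi_side_um=100.0)
        with pytest.raises(ValueError, match=">= 4"):
            tessellate(f)


class TestDensityAt:
    def test_uniform_lattice_matches_analytic_density(self, uniform_mosaic):
        tess = tessellate(uniform_mosaic)
        c = uniform_mosaic.roi_side_um / 2
        d, win = density_at((c, c), uniform_mosaic, tess, k=150)
        assert d == pytest.approx(190_000.0, rel=0.02)
        assert win > 0

    def test_corner_point_is_missing(self, uniform_mosaic):
        tess = tessellate(uniform_mosaic)
        d, win = density_at((1.0, 1.0), uniform_mosaic, tess, k=150)
        assert np.isnan(d) and np.isnan(win)

    def test_k_exceeding_cone_count_is_missing(self, uniform_mosaic):
        tess = tessellate(uniform_mosaic)
        c = uniform_mosaic.roi_side_um / 2
        d, _ = density_at((c, c), uniform_mosaic, tess, k=len(uniform_mosaic) + 10)
        assert np.isnan(d)

    def test_point_outside_roi_rejected(self, uniform_mosaic):
        with pytest.raises(ValueError, match="outside"):
            density_at((-5.0, 10.0), uniform_mosaic, k=150)

    def test_translation_invariance(self):
        f, _ = hex_field(density_per_mm2=190_000.0, roi_um=80.0)
        rng = np.random.default_rng(0)
        pts = f.points + rng.normal(0, 0.5, f.points.shape)
        big = 160.0
        base = ConeField(points=pts + 40.0 / 0.25, um_per_pixel=0.25, roi_side_um=big)
        shift_px = 32.0
        moved = ConeField(points=pts + 40.0 / 0.25 + shift_px, um_per_pixel=0.25,
                          roi_side_um=big + shift_px * 0.25)
        p = (big / 2, big / 2)
        d0, w0 = density_at(p, base, k=60)
        d1, w1 = density_at((p[0] + shift_px * 0.25, p[1] + shift_px * 0.25), moved, k=60)
        assert d1 == pytest.approx(d0, rel=1e-9)
        assert w1 == w0


class TestComputeDensityMatrix:
    def test_uniform_map_is_flat_and_unbiased(self, uniform_mosaic):
        dm = compute_density_matrix(uniform_mosaic, k=150, stride=8, edge_margin_um=10)
        vals = dm.values[dm.valid]
        assert vals.size > 50
        assert np.all(np.abs(vals / 190_000.0 - 1) < 0.02)
        assert vals.std() / vals.mean() < 0.02

    def test_stride_subsampling_consistency(self):
        f, _ = hex_field(density_per_mm2=190_000.0, roi_um=60.0)
        rng = np.random.default_rng(1)
        f = ConeField(points=np.clip(f.points + rng.normal(0, 0.8, f.points.shape),
                                     0, f.roi_side_px),
                      um_per_pixel=f.um_per_pixel, roi_side_um=f.roi_side_um)
        dm1 = compute_density_matrix(f, k=60, stride=2)
        dm4 = compute_density_matrix(f, k=60, stride=4)
        sub = dm1.values[::2, ::2]
        assert np.array_equal(np.isnan(sub), np.isnan(dm4.values))
        assert np.allclose(sub, dm4.values, rtol=1e-12, equal_nan=True)

    def test_common_scale_choice_changes_density_below_half_percent(self):
        f, _ = hex_field(density_per_mm2=180_000.0, roi_um=80.0)
        rng = np.random.default_rng(2)
        f = ConeField(points=np.clip(f.points + rng.normal(0, 0.8, f.points.shape),
                                     0, f.roi_side_px),
                      um_per_pixel=f.um_per_pixel, roi_side_um=f.roi_side_um)
        from conemetrics import rescale_to_common
        dm_fine = compute_density_matrix(f, k=100, stride=16)  # 0.25 µm/px
        dm_coarse = compute_density_matrix(rescale_to_common(f, 0.5), k=100, stride=8)
        both = dm_fine.valid & dm_coarse.valid
        assert both.sum() > 20
        rel = np.abs(dm_fine.values[both] / dm_coarse.values[both] - 1)
        assert rel.max() < 0.005

    def test_infeasible_k_gives_all_missing(self):
        f, _ = hex_field(density_per_mm2=150_000.0, roi_um=40.0)
        dm = compute_density_matrix(f, k=len(f) + 1, stride=8)
        assert not dm.valid.any()

    def test_window_growth_monotone_containment(self, uniform_mosaic):
        # enlarging the window never removes a fully-contained cell
        from conemetrics.density_map import _chebyshev_radii, tessellate as tess_fn
        tess = tess_fn(uniform_mosaic)
        p = np.array([60.0, 60.0]) / uniform_mosaic.um_per_pixel
        r = _chebyshev_radii(tess.bbox, p[0], p[1])
        prev = np.zeros(len(r), dtype=bool)
        for half in np.linspace(5, 200, 40):
            cur = r < half
            assert (prev <= cur).all()
            prev = cur


class TestCropAndAngular:
    def test_crop_revalidates_against_crop_bounds(self):
        f = generate_mosaic(MosaicParams(
            peak_density=190_000.0, falloff_scale=1e6, roi_side=200.0,
            position_jitter_sd=0.25, seed=8))
        dm = compute_density_matrix(f, k=150, stride=16, edge_margin_um=10)
        sub = crop_density_matrix(dm, 120.0)
        # valid cells of the crop lie a window-half-side + margin inside the crop
        rows, cols = np.nonzero(sub.valid)
        xs, ys = sub.x_um()[cols], sub.y_um()[rows]
        x0, x1 = sub.x_um()[0], sub.x_um()[-1]
        fit = np.minimum(np.minimum(xs - x0, x1 - xs), np.minimum(ys - x0, x1 - ys))
        assert (sub.window_um[rows, cols] / 2 + 10 <= fit + 1e-9).all()
        # values are inherited, not recomputed
        assert np.isfinite(sub.values[sub.valid]).all()

    def test_angular_conversion_value(self):
        scale = ScaleInfo.from_axial_length(24.0, 0.25)
        assert to_angular(187_000.0, scale) == pytest.approx(15_690.0, rel=1e-3)
        assert to_angular(0.0, scale) == 0.0
        assert to_angular(2.0, scale) == pytest.approx(2 * to_angular(1.0, scale))

    def test_angular_requires_scale(self):
        with pytest.raises(ValueError):
            to_angular(1000.0, None)
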