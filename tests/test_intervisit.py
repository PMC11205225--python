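import numpy as np
import pytest

from conemetrics import (
    align_at_cdc,
    composite_profile,
    cross_section,
    difference_map,
)
from conemetrics.intervisit import Profile

from conftest import make_dm


def peak_matrix(n=61, grid=1.0, center=None, peak=180_000.0, sigma=15.0, floor=0.0):
    if center is None:
        center = ((n - 1) / 2 * grid, (n - 1) / 2 * grid)
    x = np.arange(n) * grid
    xx, yy = np.meshgrid(x, x)
    r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    return make_dm(floor + peak * np.exp(-r2 / (2 * sigma**2)), grid_um=grid)


class TestAlignAndDifference:
    def test_identical_matrices_identity_translation_zero_map(self):
        dm = peak_matrix()
        pair = align_at_cdc(dm, dm)
        assert pair.shift_cells == (0, 0)
        diff = difference_map(pair, extent_um=40.0)
        assert np.allclose(diff.values[diff.valid], 0.0)

    def test_shifted_copy_cancels_after_alignment(self):
        a = peak_matrix(n=81, center=(40.0, 40.0))
        b = make_dm(a.values, grid_um=a.grid_um, origin=(20.0, -7.0))
        pair = align_at_cdc(a, b)
        diff = difference_map(pair, extent_um=40.0)
        assert diff.valid.any()
        assert np.allclose(diff.values[diff.valid], 0.0, atol=1e-9)

    def test_cdcs_coincide_after_alignment(self):
        a = peak_matrix(n=81, center=(36.0, 44.0))
        b = peak_matrix(n=81, center=(47.0, 31.0))
        pair = align_at_cdc(a, b)
        from conemetrics import find_cdc
        c1, _ = find_cdc(a)
        c2, _ = find_cdc(b)
        # translation in whole cells: residual under one cell
        assert abs((c2[0] - c1[0]) / a.grid_um - pair.shift_cells[1]) <= 0.5 + 1e-9
        assert abs((c2[1] - c1[1]) / a.grid_um - pair.shift_cells[0]) <= 0.5 + 1e-9

    def test_constant_offset_gives_constant_map(self):
        a = peak_matrix()
        b = make_dm(a.values + 5000.0, grid_um=a.grid_um)
        diff = difference_map(align_at_cdc(a, b), extent_um=40.0)
        assert np.allclose(diff.values[diff.valid], 5000.0)

    def test_antisymmetry(self):
        a = peak_matrix(n=61, center=(28.0, 30.0))
        b = make_dm(a.values * 1.04, grid_um=a.grid_um)
        d_ab = difference_map(align_at_cdc(a, b), extent_um=30.0)
        d_ba = difference_map(align_at_cdc(b, a), extent_um=30.0)
        assert np.allclose(d_ab.values, -d_ba.values, equal_nan=True)

    def test_small_overlap_warns_and_crops(self):
        a = peak_matrix(n=31)
        with pytest.warns(UserWarning, match="overlap"):
            diff = difference_map(align_at_cdc(a, a), extent_um=300.0)
        assert diff.shape == a.shape

    def test_grid_mismatch_rejected(self):
        a = peak_matrix(grid=1.0)
        b = peak_matrix(grid=2.0)
        with pytest.raises(ValueError, match="grid"):
            align_at_cdc(a, b)


class TestCrossSection:
    def test_constant_map_constant_bins(self):
        a = peak_matrix()
        b = make_dm(a.values + 1234.0, grid_um=a.grid_um)
        with pytest.warns(UserWarning):
            diff = difference_map(align_at_cdc(a, b), extent_um=100.0)
        for meridian in ("horizontal", "vertical"):
            prof = cross_section(diff, meridian, bin_um=5.0)
            assert np.allclose(prof.mean, 1234.0)
            assert (prof.n >= 1).all()

    def test_zero_map_zero_profile(self):
        a = peak_matrix()
        diff = difference_map(align_at_cdc(a, a), extent_um=40.0)
        prof = cross_section(diff, "horizontal")
        assert np.allclose(prof.mean, 0.0)

    def test_linear_ramp_bin_means_match_closed_form(self):
        n, grid = 81, 1.0
        base = peak_matrix(n=n, grid=grid, center=(40.0, 40.0))
        ramp = 100.0 * np.arange(n)[None, :] * np.ones((n, 1))
        b = make_dm(base.values + ramp, grid_um=grid)
        diff = difference_map(align_at_cdc(base, b), extent_um=40.0)
        prof = cross_section(diff, "horizontal", bin_um=5.0)
        cdc_col_x = 40.0  # symmetric peak; ramp weighting shifts CDC < 1 cell
        # mean of 100·x over each 5-µm bin equals 100·(bin center + cdc x)
        expect = 100.0 * (prof.bin_centers_um + cdc_col_x)
        assert np.allclose(prof.mean, expect, atol=100.0 * 3)

    def test_bin_containing_cdc_is_centered(self):
        a = peak_matrix()
        diff = difference_map(align_at_cdc(a, a), extent_um=30.0)
        prof = cross_section(diff, "horizontal", bin_um=5.0)
        assert 0.0 in prof.bin_centers_um
        assert np.all(np.diff(prof.bin_centers_um) == 5.0)


class TestCompositeProfile:
    def p(self, means, centers=None, bin_um=5.0):
        means = np.asarray(means, float)
        if centers is None:
            centers = (np.arange(len(means)) - len(means) // 2) * bin_um
        return Profile(np.asarray(centers, float), means,
                       np.zeros_like(means), np.ones(len(means), int), bin_um)

    def test_identical_profiles_mean_equals_sd_zero(self):
        prof = self.p([1.0, 2.0, 3.0])
        comp = composite_profile([prof, prof])
        assert np.allclose(comp.mean, prof.mean)
        assert np.allclose(comp.sd, 0.0)
        assert (comp.n == 2).all()

    def test_plus_minus_c_gives_zero_mean_sd_c_sqrt2(self):
        c = 750.0
        comp = composite_profile([self.p([c, c, c]), self.p([-c, -c, -c])])
        assert np.allclose(comp.mean, 0.0)
        assert np.allclose(comp.sd, c * np.sqrt(2.0))

    def test_partial_overlap_tracks_n(self):
        a = self.p([1.0, 1.0, 1.0], centers=[-5.0, 0.0, 5.0])
        b = self.p([3.0, 3.0, 3.0], centers=[0.0, 5.0, 10.0])
        comp = composite_profile([a, b])
        assert dict(zip(comp.bin_centers_um, comp.n)) == {
            -5.0: 1, 0.0: 2, 5.0: 2, 10.0: 1}

    def test_disjoint_bins_rejected(self):
        a = self.p([1.0], centers=[0.0])
        b = self.p([1.0], centers=[50.0])
        with pytest.raises(ValueError, match="disjoint"):
            composite_profile([a, b])

    def test_between_subject_sd_tracks_eccentricity_structure(self):
        # cohorts whose between-subject spread shrinks with eccentricity:
        # difference profiles c_i·exp(−|x|/a) → composite SD larger at CDC
        x = np.arange(-30, 31, 5, dtype=float)
        rng = np.random.default_rng(4)
        profs = [self.p(c * np.exp(-np.abs(x) / 20.0), centers=x)
                 for c in rng.normal(0, 2000.0, 8)]
        comp = composite_profile(profs)
        edge = comp.sd[np.abs(comp.bin_centers_um) >= 25.0].max()
        center = comp.sd[comp.bin_centers_um == 0.0][0]
        assert edge <= center
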