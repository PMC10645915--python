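"""Tomographic model: exact line integrals, adjointness, PSF conservation."""

import numpy as np
import pytest

from petlesionsim.core import ImageVolume, VoxelGrid, LAC
from petlesionsim.errors import GeometryError, ValidationError
from petlesionsim.projector import (
    PSFModel,
    Sinogram,
    SinogramGeometry,
    apply_psf,
    attenuation_factors,
    back_project,
    default_geometry,
    forward_project,
    system_matrix,
)

from conftest import antialiased_disk, uniform_disk


def centered_geometry(grid, n_angles):
    """Odd radial count so one bin sits exactly at radial offset 0."""
    return SinogramGeometry(
        n_radial=97, n_angles=n_angles, n_slices=grid.shape[2],
        radial_bin_mm=grid.voxel_size_mm[0],
    )


class TestForwardProject:
    def test_zero_image_gives_zero_sinogram(self, grid64, geom48):
        img = ImageVolume(grid64, np.zeros(grid64.shape))
        assert forward_project(img, geom48).values.sum() == 0.0

    @pytest.mark.parametrize("angle_index", range(8))
    def test_central_ray_through_disk_matches_chord(self, grid64, angle_index):
        geom = centered_geometry(grid64, 8)
        R = 40.0
        sino = forward_project(antialiased_disk(grid64, R), geom)
        i0 = int(np.argmin(np.abs(geom.radial_offsets_mm)))
        assert geom.radial_offsets_mm[i0] == 0.0
        chord = sino.values[i0, angle_index, 0]
        assert chord == pytest.approx(2 * R, abs=grid64.voxel_size_mm[0])

    def test_linearity(self, grid64, geom48):
        rng = np.random.default_rng(1)
        f = ImageVolume(grid64, rng.random(grid64.shape))
        g = ImageVolume(grid64, rng.random(grid64.shape))
        both = forward_project(ImageVolume(grid64, f.values + g.values), geom48)
        sep = forward_project(f, geom48).values + forward_project(g, geom48).values
        np.testing.assert_allclose(both.values, sep, rtol=1e-10)

    def test_rectangle_matches_width_over_cos(self, grid64):
        # voxel-aligned uniform rectangle: at theta=0 every ray inside its x-range
        # integrates the full y-height; at theta=pi/2 the full x-width
        geom = SinogramGeometry(97, 2, grid64.shape[2], grid64.voxel_size_mm[0])
        vals = np.zeros(grid64.shape)
        vals[24:40, 20:44, :] = 1.0  # 32 mm wide (x), 48 mm tall (y)
        sino = forward_project(ImageVolume(grid64, vals), geom)
        i0 = int(np.argmin(np.abs(geom.radial_offsets_mm)))
        vox = grid64.voxel_size_mm[0]
        assert sino.values[i0, 0, 0] == pytest.approx(48.0, abs=vox)
        assert sino.values[i0, 1, 0] == pytest.approx(32.0, abs=vox)

    def test_slice_separability(self, grid64, geom48):
        rng = np.random.default_rng(2)
        vals = rng.random(grid64.shape)
        sino = forward_project(ImageVolume(grid64, vals), geom48)
        for k in (0, 2):
            only_k = np.zeros_like(vals)
            only_k[:, :, k] = vals[:, :, k]
            sk = forward_project(ImageVolume(grid64, only_k), geom48)
            np.testing.assert_allclose(sk.values[:, :, k], sino.values[:, :, k])
            assert sk.values[:, :, [j for j in range(4) if j != k]].sum() == 0.0

    def test_slice_count_mismatch_raises(self, grid64):
        bad = SinogramGeometry(96, 48, 9, 2.0)
        with pytest.raises(GeometryError):
            forward_project(ImageVolume(grid64, np.zeros(grid64.shape)), bad)

    def test_insufficient_radial_coverage_raises(self, grid64):
        bad = SinogramGeometry(10, 48, grid64.shape[2], 2.0)
        with pytest.raises(GeometryError):
            forward_project(ImageVolume(grid64, np.zeros(grid64.shape)), bad)


class TestBackProject:
    def test_zero_sinogram_gives_zero_image(self, grid64, geom48):
        sino = Sinogram(geom48, np.zeros(geom48.shape))
        assert back_project(sino, grid64).values.sum() == 0.0

    def test_adjointness_20_random_pairs(self, grid64, geom48):
        A = system_matrix(grid64, geom48)
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.random(A.shape[1])
            y = rng.random(A.shape[0])
            lhs = float((A @ x) @ y)
            rhs = float(x @ (A.T @ y))
            assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_impulse_backprojects_onto_traced_ray(self, grid64, geom48):
        # independent oracle: march along the ray in small steps and mark voxels
        irad, iang = 60, 7
        sino_vals = np.zeros(geom48.shape)
        sino_vals[irad, iang, 0] = 1.0
        img = back_project(Sinogram(geom48, sino_vals), grid64)
        support = set(map(tuple, np.argwhere(img.values[:, :, 0] > 1e-12)))

        theta = geom48.angles[iang]
        s = geom48.radial_offsets_mm[irad]
        cx = grid64.origin_mm[0] + (grid64.shape[0] - 1) / 2 * grid64.voxel_size_mm[0]
        cy = grid64.origin_mm[1] + (grid64.shape[1] - 1) / 2 * grid64.voxel_size_mm[1]
        p0 = np.array([cx + s * np.cos(theta), cy + s * np.sin(theta)])
        d = np.array([-np.sin(theta), np.cos(theta)])
        marked = set()
        for t in np.arange(-200, 200, 0.05):
            p = p0 + t * d
            i = int(np.floor((p[0] - (grid64.origin_mm[0] - 1.0)) / 2.0))
            j = int(np.floor((p[1] - (grid64.origin_mm[1] - 1.0)) / 2.0))
            if 0 <= i < 64 and 0 <= j < 64:
                marked.add((i, j))
        # fine marching may miss corner voxels the ray clips over < 0.05 mm
        slivers = support - marked
        assert len(slivers) <= 2
        for (i, j) in slivers:
            assert img.values[i, j, 0] < 0.1  # sub-0.1 mm intersection length
        assert marked - support == set()


class TestAttenuationFactors:
    def test_zero_mu_gives_unit_factors(self, grid64, geom48):
        mu = ImageVolume(grid64, np.zeros(grid64.shape), LAC)
        np.testing.assert_array_equal(attenuation_factors(mu, geom48).values, 1.0)

    def test_uniform_disk_closed_form(self):
        grid = VoxelGrid.centered((128, 128, 1), (2.0, 2.0, 2.0))
        geom = SinogramGeometry(183, 8, 1, 2.0)
        mu = uniform_disk(grid, 100.0, 0.096, quantity=LAC)
        f = attenuation_factors(mu, geom)
        i0 = int(np.argmin(np.abs(geom.radial_offsets_mm)))
        expected = np.exp(-0.096 * 2 * 100.0 / 10.0)  # exp(-1.92)
        assert f.values[i0, 0, 0] == pytest.approx(expected, rel=0.01)

    def test_monotone_in_mu(self, grid64, geom48):
        rng = np.random.default_rng(3)
        base = rng.random(grid64.shape) * 0.05
        more = base.copy()
        more[30, 30, 1] += 0.05
        f0 = attenuation_factors(ImageVolume(grid64, base, LAC), geom48).values
        f1 = attenuation_factors(ImageVolume(grid64, more, LAC), geom48).values
        assert np.all(f1 <= f0 + 1e-15)

    def test_non_lac_input_rejected(self, grid64, geom48):
        act = ImageVolume(grid64, np.ones(grid64.shape), "activity")
        with pytest.raises(ValidationError):
            attenuation_factors(act, geom48)


class TestApplyPSF:
    def test_tiny_fwhm_is_identity(self, grid64):
        rng = np.random.default_rng(4)
        img = ImageVolume(grid64, rng.random(grid64.shape))
        out = apply_psf(img, PSFModel(0.5))
        np.testing.assert_array_equal(out.values, img.values)

    def test_delta_has_requested_fwhm(self):
        grid = VoxelGrid.centered((65, 65, 5), (2.0, 2.0, 2.0))
        vals = np.zeros(grid.shape)
        vals[32, 32, 2] = 1.0
        fwhm = 6.0
        out = apply_psf(ImageVolume(grid, vals), PSFModel(fwhm))
        prof = out.values[:, 32, 2]
        half = prof.max() / 2
        above = np.where(prof >= half)[0]
        # linear interpolation of the half-max crossings
        lo = above[0] - (half - prof[above[0]]) / (prof[above[0] - 1] - prof[above[0]])
        hi = above[-1] + (half - prof[above[-1]]) / (prof[above[-1] + 1] - prof[above[-1]])
        measured = (hi - lo) * grid.voxel_size_mm[0]
        assert measured == pytest.approx(fwhm, abs=grid.voxel_size_mm[0] / 2)

    def test_sum_conserved(self, grid64):
        rng = np.random.default_rng(5)
        img = ImageVolume(grid64, rng.random(grid64.shape))
        out = apply_psf(img, PSFModel(8.0))
        assert out.values.sum() == pytest.approx(img.values.sum(), rel=1e-6)


class TestSinogramContracts:
    def test_factor_content_rejects_values_above_one(self, geom48):
        vals = np.full(geom48.shape, 1.5)
        with pytest.raises(ValidationError):
            Sinogram(geom48, vals, "factors")

    def test_negative_values_rejected(self, geom48):
        vals = np.full(geom48.shape, -1.0)
        with pytest.raises(ValidationError):
            Sinogram(geom48, vals, "counts")

    def test_default_geometry_covers_diagonal(self, grid64):
        g = default_geometry(grid64)
        diag = np.hypot(64 * 2.0, 64 * 2.0)
        assert g.n_radial * g.radial_bin_mm >= diag
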