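"""Lesion rasterization, calibration chain, scatter, noise, merge modes."""

import numpy as np
import pytest

from petlesionsim.core import ImageVolume, LAC, VoxelGrid
from petlesionsim.errors import (
    ConfigError,
    DomainError,
    EmptyROIError,
    ValidationError,
)
from petlesionsim.insertion import (
    AcquisitionModel,
    LesionSpec,
    assign_activity,
    estimate_scatter,
    lesion_to_expected_counts,
    merge_into_patient,
    rasterize_roi,
    sample_poisson,
    simulate_acquisition,
)
from petlesionsim.mumaps import CTAC, MuMap
from petlesionsim.projector import EXPECTED_COUNTS, Sinogram, default_geometry


def sphere_spec(center=(0.0, 0.0, 0.0), radius=4.0, mode="absolute", value=10.0):
    return LesionSpec(
        shape="sphere", activity_mode=mode, value=value,
        center_mm=center, radius_mm=radius,
    )


@pytest.fixture(scope="module")
def grid():
    return VoxelGrid.centered((32, 32, 8), (2.0, 2.0, 2.0))


@pytest.fixture(scope="module")
def water_mu(grid):
    return MuMap(ImageVolume(grid, np.full(grid.shape, 0.0), LAC), CTAC)


class TestRasterizeROI:
    def test_sphere_volume_close_to_analytic(self, grid):
        r = 4.0
        mask = rasterize_roi(sphere_spec(radius=r), grid)
        count = int(mask.values.sum())
        analytic = (4 / 3) * np.pi * r**3 / np.prod(grid.voxel_size_mm)
        # brute-force voxel-center oracle over the bounding box
        brute = 0
        for x in grid.voxel_centers(0):
            for y in grid.voxel_centers(1):
                for z in grid.voxel_centers(2):
                    if x * x + y * y + z * z <= r * r:
                        brute += 1
        assert count == brute
        surface = 4 * np.pi * r**2 * max(grid.voxel_size_mm) / np.prod(grid.voxel_size_mm)
        assert abs(count - analytic) <= surface

    def test_atlas_mode_exact_label_equality(self, small_bundle):
        label = small_bundle.atlas.id_of("fusiform")
        spec = LesionSpec(
            shape="atlas_region", activity_mode="absolute", value=1.0,
            region_label=label,
        )
        mask = rasterize_roi(spec, small_bundle.grid, small_bundle.atlas)
        np.testing.assert_array_equal(
            mask.values > 0, small_bundle.atlas.labels == label
        )

    def test_sphere_outside_grid_is_empty_roi(self, grid):
        with pytest.raises(EmptyROIError):
            rasterize_roi(sphere_spec(center=(500.0, 0.0, 0.0)), grid)


class TestAssignActivity:
    def test_absolute_mode(self, grid):
        mask = rasterize_roi(sphere_spec(value=10.0), grid)
        act = assign_activity(mask, sphere_spec(value=10.0))
        assert set(np.unique(act.values)) == {0.0, 10.0}

    def test_lbr_over_uniform_background(self, grid):
        spec = sphere_spec(mode="lbr", value=2.0)
        mask = rasterize_roi(spec, grid)
        bg = ImageVolume(grid, np.full(grid.shape, 5.0))
        act = assign_activity(mask, spec, bg)
        assert act.values.max() == pytest.approx(10.0)

    def test_lbr_needs_background(self, grid):
        spec = sphere_spec(mode="lbr", value=2.0)
        mask = rasterize_roi(spec, grid)
        with pytest.raises(ConfigError):
            assign_activity(mask, spec)

    def test_lbr_over_zero_background_rejected(self, grid):
        spec = sphere_spec(mode="lbr", value=2.0)
        mask = rasterize_roi(spec, grid)
        bg = ImageVolume(grid, np.zeros(grid.shape))
        with pytest.raises(DomainError):
            assign_activity(mask, spec, bg)


class TestExpectedCounts:
    def test_zero_lesion_zero_sinogram(self, grid, water_mu):
        geom = default_geometry(grid)
        lesion = ImageVolume(grid, np.zeros(grid.shape))
        out = lesion_to_expected_counts(lesion, water_mu, AcquisitionModel(), None, geom)
        assert out.values.sum() == 0.0

    def test_factor_collapse_without_attenuation(self, grid, water_mu):
        geom = default_geometry(grid)
        rng = np.random.default_rng(0)
        lesion = ImageVolume(grid, rng.random(grid.shape))
        acq = AcquisitionModel(duration_s=100.0, sensitivity=0.01)
        out = lesion_to_expected_counts(lesion, water_mu, acq, None, geom)
        from petlesionsim.projector import forward_project

        li = forward_project(lesion, geom)
        np.testing.assert_allclose(out.values, li.values * 0.01 * 100.0, rtol=1e-12)

    def test_linear_in_duration(self, grid, water_mu):
        geom = default_geometry(grid)
        rng = np.random.default_rng(1)
        lesion = ImageVolume(grid, rng.random(grid.shape))
        one = lesion_to_expected_counts(
            lesion, water_mu, AcquisitionModel(duration_s=100.0), None, geom
        )
        two = lesion_to_expected_counts(
            lesion, water_mu, AcquisitionModel(duration_s=200.0), None, geom
        )
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)

    def test_end_to_end_linearity_pre_noise(self, small_bundle):
        # expected counts of (background + lesion) = sum of the separate chains
        geom = default_geometry(small_bundle.grid, n_angles=48)
        mu = MuMap(small_bundle.mu_true.copy(), CTAC)
        acq = AcquisitionModel(scatter_fraction=0.0)
        lesion = ImageVolume(
            small_bundle.grid,
            np.where(small_bundle.atlas.labels == 4, 8.0, 0.0),
        )
        both = ImageVolume(
            small_bundle.grid, small_bundle.emission.values + lesion.values
        )
        e_both = lesion_to_expected_counts(both, mu, acq, None, geom)
        e_bg = lesion_to_expected_counts(small_bundle.emission, mu, acq, None, geom)
        e_les = lesion_to_expected_counts(lesion, mu, acq, None, geom)
        np.testing.assert_allclose(
            e_both.values, e_bg.values + e_les.values, rtol=1e-9, atol=1e-12
        )


class TestScatter:
    def make_trues(self, geom, value=100.0):
        vals = np.zeros(geom.shape)
        vals[geom.n_radial // 2, :, :] = value
        return Sinogram(geom, vals, EXPECTED_COUNTS)

    def test_zero_fraction_zero_scatter(self, grid):
        geom = default_geometry(grid)
        trues = self.make_trues(geom)
        out = estimate_scatter(trues, AcquisitionModel(scatter_fraction=0.0))
        assert out.values.sum() == 0.0

    def test_fraction_exact(self, grid):
        geom = default_geometry(grid)
        trues = self.make_trues(geom)
        acq = AcquisitionModel(scatter_fraction=0.3)
        sc = estimate_scatter(trues, acq)
        frac = sc.values.sum() / (trues.values.sum() + sc.values.sum())
        assert frac == pytest.approx(0.3, abs=1e-9)

    def test_scatter_is_smoother_than_trues(self, grid):
        geom = default_geometry(grid)
        trues = self.make_trues(geom)
        sc = estimate_scatter(trues, AcquisitionModel(scatter_fraction=0.3))
        d_true = np.abs(np.diff(trues.values[:, 0, 0])).max()
        d_sc = np.abs(np.diff(sc.values[:, 0, 0])).max()
        assert d_sc < d_true


class TestPoisson:
    def test_zero_expectation_zero_counts(self, grid):
        geom = default_geometry(grid)
        expected = Sinogram(geom, np.zeros(geom.shape), EXPECTED_COUNTS)
        assert sample_poisson(expected, seed=0).values.sum() == 0

    def test_seeded_reproducibility(self, grid):
        geom = default_geometry(grid)
        expected = Sinogram(geom, np.full(geom.shape, 50.0), EXPECTED_COUNTS)
        a = sample_poisson(expected, seed=13)
        b = sample_poisson(expected, seed=13)
        np.testing.assert_array_equal(a.values, b.values)

    def test_poisson_moments(self):
        geom_shape_bins = 10_000
        from petlesionsim.projector import SinogramGeometry

        geom = SinogramGeometry(100, 100, 1, 1.0)
        expected = Sinogram(geom, np.full(geom.shape, 100.0), EXPECTED_COUNTS)
        counts = sample_poisson(expected, seed=99).values
        se = np.sqrt(100.0 / geom_shape_bins)
        assert abs(counts.mean() - 100.0) < 3 * se
        assert 0.9 < counts.var() / counts.mean() < 1.1


class TestMerge:
    def setup_sinos(self, grid, seed=0):
        geom = default_geometry(grid)
        rng = np.random.default_rng(seed)
        bg = Sinogram(geom, rng.integers(0, 50, geom.shape), "counts")
        lesion = Sinogram(geom, 20.0 * (rng.random(geom.shape) < 0.1), EXPECTED_COUNTS)
        scatter = Sinogram(geom, np.full(geom.shape, 0.5), EXPECTED_COUNTS)
        return geom, bg, lesion, scatter

    def test_with_background_totals_add(self, grid):
        geom, bg, lesion, scatter = self.setup_sinos(grid)
        res = merge_into_patient(bg, lesion, scatter, "with_background", seed=5)
        draw_total = res.merged_counts.values.sum() - bg.values.sum()
        only = merge_into_patient(None, lesion, scatter, "lesion_only", seed=5)
        assert draw_total == only.merged_counts.values.sum()

    def test_lesion_only_total_within_poisson_range(self, grid):
        geom, _, lesion, _ = self.setup_sinos(grid)
        zero_scatter = Sinogram(geom, np.zeros(geom.shape), EXPECTED_COUNTS)
        res = merge_into_patient(None, lesion, zero_scatter, "lesion_only", seed=2)
        lam = lesion.values.sum()
        assert abs(res.merged_counts.values.sum() - lam) < 3 * np.sqrt(lam)

    def test_replace_preserves_bins_outside_footprint(self, grid):
        geom, bg, lesion, scatter = self.setup_sinos(grid)
        res = merge_into_patient(bg, lesion, scatter, "replace", seed=7)
        fp = lesion.values > 1e-3 * lesion.values.max()
        np.testing.assert_array_equal(
            res.merged_counts.values[~fp], bg.values[~fp]
        )

    def test_counts_are_nonnegative_integers(self, grid):
        geom, bg, lesion, scatter = self.setup_sinos(grid)
        for mode in ("with_background", "lesion_only", "replace"):
            res = merge_into_patient(bg, lesion, scatter, mode, seed=1)
            assert np.issubdtype(res.merged_counts.values.dtype, np.integer)
            assert res.merged_counts.values.min() >= 0

    def test_modes_requiring_background(self, grid):
        geom, _, lesion, scatter = self.setup_sinos(grid)
        for mode in ("with_background", "replace"):
            with pytest.raises(ConfigError):
                merge_into_patient(None, lesion, scatter, mode, seed=1)


class TestSimulateAcquisition:
    def test_zero_emission_zero_counts(self, grid, water_mu):
        geom = default_geometry(grid)
        em = ImageVolume(grid, np.zeros(grid.shape))
        counts = simulate_acquisition(em, water_mu, AcquisitionModel(), None, geom, seed=1)
        assert counts.values.sum() == 0

    def test_expected_scale_linear_in_emission(self, grid, water_mu):
        geom = default_geometry(grid)
        rng = np.random.default_rng(3)
        em = ImageVolume(grid, rng.random(grid.shape))
        _, e1 = simulate_acquisition(
            em, water_mu, AcquisitionModel(), None, geom, seed=1, return_expected=True
        )
        em2 = ImageVolume(grid, 2 * em.values)
        _, e2 = simulate_acquisition(
            em2, water_mu, AcquisitionModel(), None, geom, seed=1, return_expected=True
        )
        np.testing.assert_allclose(e2.values, 2 * e1.values, rtol=1e-9)
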