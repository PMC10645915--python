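import dataclasses

import numpy as np
import pytest

from petlesionsim.core import VoxelGrid, ImageVolume
from petlesionsim.phantom import PhantomConfig, generate_phantom
from petlesionsim.pipeline import ExperimentConfig, run_experiment, smoke_config
from petlesionsim.projector import SinogramGeometry, default_geometry


@pytest.fixture(scope="session")
def grid64():
    return VoxelGrid.centered((64, 64, 4), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def geom48(grid64):
    return default_geometry(grid64, n_angles=48)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale phantom configuration shared by the fast unit tests."""
    return PhantomConfig(
        grid_shape=(64, 64, 8),
        voxel_size_mm=(3.0, 3.0, 3.0),
        head_radius_mm=(72.0, 88.0),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_phantom(small_config, seed=5)


@pytest.fixture(scope="session")
def smoke_cohort_result():
    """Five-subject smoke cohort, the main end-to-end fixture."""
    return run_experiment(smoke_config(master_seed=7, n_subjects=5), out_dir=None)


@pytest.fixture(scope="session")
def default_subject_result():
    """One subject at the full default grid (128x128x16, 128 angles)."""
    cfg = dataclasses.replace(ExperimentConfig(), n_subjects=1, save_images=False)
    return run_experiment(cfg, out_dir=None)


def uniform_disk(grid: VoxelGrid, radius_mm: float, value: float = 1.0,
                 quantity: str = "activity") -> ImageVolume:
    X, Y, Z = grid.meshgrid_mm()
    return ImageVolume(grid, value * ((X**2 + Y**2) <= radius_mm**2), quantity)


def antialiased_disk(grid: VoxelGrid, radius_mm: float, value: float = 1.0,
                     subsamples: int = 5) -> ImageVolume:
    """Disk with fractional edge-voxel occupancy, so its line integrals match
    the analytic chord lengths without binary rasterization jaggedness."""
    nx, ny, nz = grid.shape
    vx, vy = grid.voxel_size_mm[:2]
    offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    occ = np.zeros((nx, ny))
    xs, ys = grid.voxel_centers(0), grid.voxel_centers(1)
    for ox in offs:
        for oy in offs:
            X, Y = np.meshgrid(xs + ox * vx, ys + oy * vy, indexing="ij")
            occ += (X**2 + Y**2) <= radius_mm**2
    occ /= subsamples**2
    return ImageVolume(grid, np.repeat(occ[:, :, None], nz, axis=2) * value)
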