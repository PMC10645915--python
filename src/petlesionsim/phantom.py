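"""Analytic digital head phantom and randomized cohorts.

The phantom is a desk-scale stand-in for a clinical brain PET/CT subject:
nested ellipsoids form scalp, skull and brain; the outer brain shell (the
cortical "ribbon") is split into named angular sectors mimicking a
FreeSurfer cortical parcellation, with one deep gray region (the fusiform
analogue) placed far from the skull so near-bone vs deep-bias gradients can
be probed.  Emission is piecewise constant per region with gray matter
hotter than white; the CT volume assigns air/soft/bone Hounsfield values
spanning both segments of the bilinear HU->LAC model, and the ground-truth
attenuation map is exactly its conversion.

Cohorts emulate inter-subject variability with seeded jitter of head size,
skull thickness and regional activity.  Every output is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ACTIVITY, HOUNSFIELD, ImageVolume, LabelVolume, VoxelGrid
from .errors import ConfigError, SizingError, ValidationError
from .mumaps import BilinearParams, hu_to_lac

# FreeSurfer-style names for the default 16 cortical regions; the last one
# (fusiform) is the deep region, the rest are skull-adjacent ribbon sectors.
DEFAULT_CORTICAL_NAMES = (
    "superior_frontal",
    "rostral_middle_frontal",
    "caudal_middle_frontal",
    "frontal_pole",
    "lateral_orbitofrontal",
    "medial_orbitofrontal",
    "pars_opercularis",
    "pars_orbitalis",
    "pars_triangularis",
    "superior_parietal",
    "inferior_parietal",
    "supramarginal",
    "precuneus",
    "superior_temporal",
    "middle_temporal",
    "fusiform",
)

LABEL_SCALP = 1
LABEL_SKULL = 2
LABEL_WHITE = 3
LABEL_FUSIFORM = 4
FIRST_SECTOR_LABEL = 5


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and tissue parameters of the analytic head phantom."""

    grid_shape: tuple[int, int, int] = (128, 128, 16)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    head_radius_mm: tuple[float, float] = (72.0, 88.0)  # in-plane semi-axes
    z_semi_axis_mm: float = 120.0
    scalp_thickness_mm: float = 6.0
    skull_thickness_mm: float = 6.0
    ribbon_thickness_mm: float = 8.0
    fusiform_radius_mm: float = 15.0
    gray_white_ratio: float = 4.0
    white_activity: float = 1.0  # Bq/mL; arbitrary global scale
    n_cortical_sectors: int = 16
    skull_hu_range: tuple[float, float] = (700.0, 1200.0)
    scalp_hu_range: tuple[float, float] = (20.0, 60.0)
    brain_hu_range: tuple[float, float] = (25.0, 45.0)
    activity_jitter: float = 0.0  # per-region multiplier amplitude
    bilinear: BilinearParams = BilinearParams()

    def __post_init__(self) -> None:
        if self.n_cortical_sectors < 16:
            raise ConfigError(
                f"need >= 16 cortical sectors, got {self.n_cortical_sectors}"
            )
        if not 0.0 <= self.activity_jitter < 1.0:
            raise ConfigError("activity_jitter must be in [0, 1)")
        if self.gray_white_ratio <= 0 or self.white_activity <= 0:
            raise ConfigError("activities and ratios must be positive")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid.centered(self.grid_shape, self.voxel_size_mm)

    def validate_sizing(self) -> None:
        half = [
            self.grid_shape[a] * self.voxel_size_mm[a] / 2.0 for a in range(2)
        ]
        margin = max(self.voxel_size_mm[:2])
        if self.head_radius_mm[0] + margin > half[0] or \
                self.head_radius_mm[1] + margin > half[1]:
            raise SizingError(
                f"head semi-axes {self.head_radius_mm} do not fit on a "
                f"{self.grid_shape[:2]} x {self.voxel_size_mm[:2]} mm grid"
            )
        inner = min(self.head_radius_mm) - self.scalp_thickness_mm \
            - self.skull_thickness_mm - self.ribbon_thickness_mm
        if inner < self.fusiform_radius_mm + 2 * margin:
            raise SizingError(
                "brain interior too small for the deep region: "
                f"{inner:.1f} mm left inside the cortical ribbon"
            )


@dataclass
class PhantomBundle:
    """One synthetic subject: emission, CT, atlas and true attenuation map."""

    emission: ImageVolume
    ct_hu: ImageVolume
    atlas: LabelVolume
    mu_true: ImageVolume
    seed: int

    def __post_init__(self) -> None:
        g = self.emission.grid
        for other in (self.ct_hu, self.atlas, self.mu_true):
            g.require_same(other.grid, "phantom bundle volumes")
        skull = self.atlas.mask(self.atlas.id_of("skull"))
        if skull.any() and self.ct_hu.values[skull].min() < 300:
            raise ValidationError("skull voxels must have HU >= 300")
        brain = (self.atlas.labels >= LABEL_WHITE)
        if brain.any() and self.emission.values[brain].min() <= 0:
            raise ValidationError("brain-tissue voxels must have emission > 0")

    @property
    def grid(self) -> VoxelGrid:
        return self.emission.grid


def _ellipsoid(X, Y, Z, ax, ay, az):
    return (X / ax) ** 2 + (Y / ay) ** 2 + (Z / az) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig, seed: int) -> PhantomBundle:
    """Deterministic-under-seed head phantom (see module docstring)."""
    config.validate_sizing()
    rng = np.random.default_rng(seed)
    grid = config.grid
    X, Y, Z = grid.meshgrid_mm()

    ax, ay = config.head_radius_mm
    az = config.z_semi_axis_mm
    skin = _ellipsoid(X, Y, Z, ax, ay, az)
    t1 = config.scalp_thickness_mm
    t2 = t1 + config.skull_thickness_mm
    t3 = t2 + config.ribbon_thickness_mm
    skull_outer = _ellipsoid(X, Y, Z, ax - t1, ay - t1, az - t1)
    brain = _ellipsoid(X, Y, Z, ax - t2, ay - t2, az - t2)
    deep = _ellipsoid(X, Y, Z, ax - t3, ay - t3, az - t3)

    scalp = skin & ~skull_outer
    skull = skull_outer & ~brain
    ribbon = brain & ~deep
    r = config.fusiform_radius_mm
    fusiform = deep & (X**2 + Y**2 + (Z / 3.0) ** 2 <= r * r)
    white = deep & ~fusiform

    # angular ribbon sectors; superior_frontal is the +y ("frontal") sector
    n_ribbon = config.n_cortical_sectors - 1
    phi = np.arctan2(X, Y)  # 0 at +y, increases clockwise
    sector = np.floor((phi + np.pi) / (2 * np.pi) * n_ribbon).astype(np.int64)
    sector = np.clip(sector, 0, n_ribbon - 1)
    # rotate so sector index 0 is centered on +y
    sector = (sector - n_ribbon // 2) % n_ribbon

    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[scalp] = LABEL_SCALP
    labels[skull] = LABEL_SKULL
    labels[white] = LABEL_WHITE
    labels[fusiform] = LABEL_FUSIFORM
    labels[ribbon] = FIRST_SECTOR_LABEL + sector[ribbon]

    names = {LABEL_SCALP: "scalp", LABEL_SKULL: "skull", LABEL_WHITE: "white_matter"}
    cortical = list(DEFAULT_CORTICAL_NAMES[: min(16, config.n_cortical_sectors)])
    while len(cortical) < config.n_cortical_sectors:
        cortical.append(f"cortical_sector_{len(cortical) + 1}")
    # last cortical name is the deep region
    names[LABEL_FUSIFORM] = cortical[-1]
    for i, name in enumerate(cortical[:-1]):
        names[FIRST_SECTOR_LABEL + i] = name
    atlas = LabelVolume(grid, labels, names)

    # Hounsfield volume: one seeded draw per tissue compartment
    hu = np.full(grid.shape, -1000.0)
    hu[scalp] = rng.uniform(*config.scalp_hu_range)
    hu[skull] = rng.uniform(*config.skull_hu_range)
    hu[brain] = rng.uniform(*config.brain_hu_range)
    ct = ImageVolume(grid, hu, HOUNSFIELD)

    # piecewise-constant emission: gray = ratio * white, optional per-region jitter
    gray_act = config.gray_white_ratio * config.white_activity
    em = np.zeros(grid.shape)
    em[white] = config.white_activity
    gray_labels = [LABEL_FUSIFORM] + [FIRST_SECTOR_LABEL + i for i in range(n_ribbon)]
    for lab in gray_labels:
        mult = 1.0
        if config.activity_jitter > 0:
            mult = rng.uniform(1 - config.activity_jitter, 1 + config.activity_jitter)
        em[labels == lab] = gray_act * mult
    if config.activity_jitter > 0:
        em[white] *= rng.uniform(1 - config.activity_jitter, 1 + config.activity_jitter)
    emission = ImageVolume(grid, em, ACTIVITY)

    mu_true = hu_to_lac(ct, config.bilinear)
    return PhantomBundle(emission, ct, atlas, mu_true, int(seed))


@dataclass(frozen=True)
class CohortJitter:
    """Per-subject variability amplitudes for :func:`cohort`."""

    head_frac: float = 0.05
    skull_frac: float = 0.20
    activity_frac: float = 0.10


def derive_subject(
    config: PhantomConfig,
    master_seed: int,
    index: int,
    jitter: CohortJitter | None = None,
) -> tuple[PhantomConfig, int]:
    """Jittered per-subject (config, seed), reproducible from the master seed."""
    jit = jitter or CohortJitter()
    rng = np.random.default_rng([int(master_seed), int(index)])
    head = rng.uniform(1 - jit.head_frac, 1 + jit.head_frac)
    skull = rng.uniform(1 - jit.skull_frac, 1 + jit.skull_frac)
    cfg = replace(
        config,
        head_radius_mm=(config.head_radius_mm[0] * head, config.head_radius_mm[1] * head),
        skull_thickness_mm=config.skull_thickness_mm * skull,
        activity_jitter=jit.activity_frac,
    )
    seed = int(rng.integers(0, 2**31))
    return cfg, seed


def cohort(
    config: PhantomConfig,
    n: int,
    master_seed: int,
    jitter: CohortJitter | None = None,
) -> list[PhantomBundle]:
    """n independent jittered subjects derived reproducibly from master_seed."""
    if n < 1:
        raise ConfigError(f"cohort size must be >= 1, got {n}")
    return [
        generate_phantom(*derive_subject(config, master_seed, i, jitter))
        for i in range(n)
    ]


def region_centroid_mm(atlas: LabelVolume, name: str) -> tuple[float, float, float]:
    """World-coordinate centroid of a named atlas region."""
    label = atlas.id_of(name)
    mask = atlas.mask(label)
    if not mask.any():
        raise ValidationError(f"region {name!r} is empty")
    idx = np.argwhere(mask).mean(axis=0)
    return tuple(
        atlas.grid.origin_mm[a] + idx[a] * atlas.grid.voxel_size_mm[a]
        for a in range(3)
    )
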