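"""Projection-space synthetic lesion insertion.

The core simulation chain: a lesion/ROI specification is rasterized on the
image grid, given an activity (absolute, or relative to the local
background via a lesion-to-background ratio), smoothed by the scanner PSF,
forward-projected, attenuated by the *true* attenuation map, scaled by
normalization and the calibration constant (sensitivity x duration) into
expected counts, augmented with a smooth scatter estimate, Poisson-sampled,
and finally added to (or substituted for) the patient background sinogram.

Everything up to the Poisson draw is linear in the activity image, so
lesions simulated separately and jointly agree exactly pre-noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.ndimage as ndi

from .core import ACTIVITY, LABEL_PROB, ImageVolume, LabelVolume, VoxelGrid
from .errors import (
    ConfigError,
    DomainError,
    EmptyROIError,
    RegionLookupError,
    ValidationError,
)
from .mumaps import MuMap
from .projector import (
    COUNTS,
    EXPECTED_COUNTS,
    PSFModel,
    Sinogram,
    SinogramGeometry,
    apply_psf,
    attenuation_factors,
    forward_project,
)

SPHERE = "sphere"
ATLAS_REGION = "atlas_region"
ABSOLUTE = "absolute"
LBR = "lbr"

WITH_BACKGROUND = "with_background"
LESION_ONLY = "lesion_only"
REPLACE = "replace"

#: replace-mode support: bins with lesion_expected above this fraction of its max
REPLACE_FOOTPRINT_REL = 1e-3


@dataclass(frozen=True)
class LesionSpec:
    """Declarative lesion/ROI description.

    A sphere (center + radius, mm) or an atlas region (integer label), with
    activity either absolute (Bq/mL) or as a lesion-to-background ratio.
    """

    shape: str
    activity_mode: str
    value: float
    center_mm: Optional[tuple[float, float, float]] = None
    radius_mm: Optional[float] = None
    region_label: Optional[int] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.shape not in (SPHERE, ATLAS_REGION):
            raise ConfigError(f"unknown lesion shape {self.shape!r}")
        if self.activity_mode not in (ABSOLUTE, LBR):
            raise ConfigError(f"unknown activity mode {self.activity_mode!r}")
        if self.value <= 0:
            raise ConfigError("lesion value must be > 0")
        if self.shape == SPHERE:
            if self.center_mm is None or self.radius_mm is None or self.radius_mm <= 0:
                raise ConfigError("sphere lesions need center_mm and radius_mm > 0")
            if self.region_label is not None:
                raise ConfigError("sphere lesions must not set region_label")
        else:
            if self.region_label is None:
                raise ConfigError("atlas_region lesions need region_label")
            if self.center_mm is not None or self.radius_mm is not None:
                raise ConfigError("atlas_region lesions must not set sphere fields")


@dataclass
class AcquisitionModel:
    """Count calibration: duration, sensitivity, scatter fraction, normalization.

    ``sensitivity`` is the expected number of detected counts per
    (Bq/mL * mm) of projected activity in one bin per second; the overall
    calibration constant is ``sensitivity * duration_s``.  ``norm`` is an
    optional per-bin efficiency factor sinogram (<= 1); None means uniform.
    """

    duration_s: float = 600.0
    sensitivity: float = 0.005
    scatter_fraction: float = 0.30
    norm: Optional[Sinogram] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sensitivity <= 0:
            raise ConfigError("duration_s and sensitivity must be > 0")
        if not 0.0 <= self.scatter_fraction < 1.0:
            raise ConfigError("scatter_fraction must be in [0, 1)")

    def norm_values(self, geom: SinogramGeometry) -> np.ndarray:
        if self.norm is None:
            return np.ones(geom.shape)
        if self.norm.geometry.shape != geom.shape:
            raise ConfigError("norm sinogram geometry does not match")
        return self.norm.values


@dataclass
class InsertionResult:
    """Outcome of merging a lesion draw into (or instead of) the background."""

    lesion_expected: Sinogram
    scatter: Sinogram
    merged_counts: Sinogram
    mode: str
    seed: int

    def __post_init__(self) -> None:
        if self.mode not in (WITH_BACKGROUND, LESION_ONLY, REPLACE):
            raise ValidationError(f"unknown merge mode {self.mode!r}")
        v = self.merged_counts.values
        if not np.issubdtype(v.dtype, np.integer):
            raise ValidationError("merged counts must be integer-valued")


def rasterize_roi(
    spec: LesionSpec, grid: VoxelGrid, atlas: Optional[LabelVolume] = None
) -> ImageVolume:
    """Binary ROI mask: voxel-center sphere membership, or exact label equality."""
    if spec.shape == SPHERE:
        X, Y, Z = grid.meshgrid_mm()
        cx, cy, cz = spec.center_mm
        d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        mask = d2 <= spec.radius_mm**2
        if not mask.any():
            raise EmptyROIError(
                f"sphere at {spec.center_mm} r={spec.radius_mm} mm covers no voxel"
            )
    else:
        if atlas is None:
            raise ConfigError("atlas_region lesions need an atlas")
        grid.require_same(atlas.grid, "ROI grid and atlas")
        if spec.region_label not in atlas.region_ids:
            raise RegionLookupError(f"atlas has no label {spec.region_label}")
        mask = atlas.labels == spec.region_label
        if not mask.any():
            raise EmptyROIError(f"atlas label {spec.region_label} is empty")
    return ImageVolume(grid, mask.astype(float), LABEL_PROB)


def assign_activity(
    mask: ImageVolume, spec: LesionSpec, background: Optional[ImageVolume] = None
) -> ImageVolume:
    """Activity image of the lesion: absolute value, or LBR x local background mean."""
    m = mask.values > 0
    if spec.activity_mode == ABSOLUTE:
        level = spec.value
    else:
        if background is None:
            raise ConfigError("lbr activity mode requires a background image")
        mask.grid.require_same(background.grid, "mask and background")
        mean_bg = float(background.values[m].mean()) if m.any() else 0.0
        if mean_bg <= 0:
            raise DomainError("lbr mode over zero background activity")
        level = spec.value * mean_bg
    return ImageVolume(mask.grid, np.where(m, level, 0.0), ACTIVITY)


def lesion_to_expected_counts(
    lesion: ImageVolume,
    mu: MuMap,
    acq: AcquisitionModel,
    psf: Optional[PSFModel],
    geom: SinogramGeometry,
) -> Sinogram:
    """Calibrated expected-count sinogram of an activity image.

    expected = P(psf * lesion) x attenuation(mu) x norm x sensitivity x duration.
    The attenuation and normalization corrections enter as multiplicative
    survival/efficiency factors <= 1.
    """
    lesion.grid.require_same(mu.grid, "lesion and attenuation map")
    smoothed = apply_psf(lesion, psf)
    li = forward_project(smoothed, geom)
    att = attenuation_factors(mu, geom)
    vals = (
        li.values
        * att.values
        * acq.norm_values(geom)
        * acq.sensitivity
        * acq.duration_s
    )
    return Sinogram(geom, vals, EXPECTED_COUNTS)


def estimate_scatter(
    trues: Sinogram, acq: AcquisitionModel, kernel_fwhm_mm: float = 80.0
) -> Sinogram:
    """Smooth scatter estimate at the configured scatter fraction.

    A broad radial Gaussian blur of the trues per (angle, slice), rescaled
    so total scatter / (total trues + total scatter) equals
    ``acq.scatter_fraction`` exactly.  A zero scatter fraction returns a
    zero sinogram.
    """
    if kernel_fwhm_mm <= 0:
        raise ConfigError("kernel_fwhm_mm must be > 0")
    sf = acq.scatter_fraction
    if sf == 0.0 or trues.values.sum() == 0.0:
        return Sinogram(trues.geometry, np.zeros(trues.geometry.shape), EXPECTED_COUNTS)
    sigma_bins = kernel_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) \
        / trues.geometry.radial_bin_mm
    blurred = ndi.gaussian_filter1d(trues.values, sigma_bins, axis=0, mode="constant")
    blurred = np.maximum(blurred, 0.0)
    target_total = sf / (1.0 - sf) * trues.values.sum()
    blurred *= target_total / blurred.sum()
    return Sinogram(trues.geometry, blurred, EXPECTED_COUNTS)


def sample_poisson(expected: Sinogram, seed: int) -> Sinogram:
    """Independent Poisson draw per bin, reproducible under the seed."""
    if np.any(expected.values < 0):
        raise ValidationError("negative expected counts")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected.values)
    return Sinogram(expected.geometry, counts, COUNTS)


def merge_into_patient(
    background: Optional[Sinogram],
    lesion_expected: Sinogram,
    scatter: Sinogram,
    mode: str,
    seed: int,
) -> InsertionResult:
    """Noise the lesion and merge it into the patient projection data.

    with_background: background counts + Poisson(lesion + scatter).
    lesion_only:     Poisson(lesion + scatter) alone.
    replace:         background counts zeroed on the lesion footprint
                     (bins above REPLACE_FOOTPRINT_REL x max), lesion draw
                     substituted there; all other bins untouched.
    """
    if mode not in (WITH_BACKGROUND, LESION_ONLY, REPLACE):
        raise ConfigError(f"unknown merge mode {mode!r}")
    if mode in (WITH_BACKGROUND, REPLACE) and background is None:
        raise ConfigError(f"mode {mode!r} requires a background sinogram")
    geom = lesion_expected.geometry
    if scatter.geometry.shape != geom.shape:
        raise ConfigError("scatter geometry does not match lesion geometry")
    draw = sample_poisson(
        Sinogram(geom, lesion_expected.values + scatter.values, EXPECTED_COUNTS), seed
    )
    if mode == LESION_ONLY:
        merged = draw.values
    elif mode == WITH_BACKGROUND:
        merged = background.values.astype(np.int64) + draw.values
    else:
        fp = lesion_expected.values > REPLACE_FOOTPRINT_REL * lesion_expected.values.max()
        merged = np.where(fp, draw.values, background.values.astype(np.int64))
    return InsertionResult(
        lesion_expected=lesion_expected,
        scatter=scatter,
        merged_counts=Sinogram(geom, merged.astype(np.int64), COUNTS),
        mode=mode,
        seed=int(seed),
    )


def simulate_acquisition(
    emission: ImageVolume,
    mu: MuMap,
    acq: AcquisitionModel,
    psf: Optional[PSFModel],
    geom: SinogramGeometry,
    seed: int,
    return_expected: bool = False,
):
    """Synthetic patient background sinogram: full chain + Poisson noise."""
    trues = lesion_to_expected_counts(emission, mu, acq, psf, geom)
    scatter = estimate_scatter(trues, acq)
    expected = Sinogram(geom, trues.values + scatter.values, EXPECTED_COUNTS)
    counts = sample_poisson(expected, seed)
    if return_expected:
        return counts, expected
    return counts
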