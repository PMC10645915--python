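"""CT-to-LAC conversion, resampling, and MR-style attenuation map families.

PET attenuation correction needs a map of 511 keV linear attenuation
coefficients (LAC, cm^-1).  CT provides it through the standard bilinear
Hounsfield conversion; MR cannot see bone directly, so MR-derived maps
(MRAC) approximate the skull in method-specific ways.  This module derives
the four classic MRAC families as controlled degradations of the ground
truth CT map:

``dixon``
    soft-tissue-only segmentation: all bone is replaced by soft tissue.
``dixonbone``
    model-based bone added back, but with a global LAC bias and a boundary
    erosion emulating the registration/segmentation losses of an atlas bone
    model.
``ute``
    short-echo-time bone segmentation: a single binary bone compartment at
    one fixed LAC, with a seeded fraction of misclassified boundary voxels.
``dl_dixon``
    deep-learning pseudo-CT: near-truth continuous map with small voxelwise
    noise; by construction the most faithful of the four.

The resulting whole-volume LAC error is ordered dixon > ute >= dixonbone >
dl_dixon under the defaults, which is the bone-fidelity ordering the
downstream bias evaluation is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.ndimage as ndi

from .core import HOUNSFIELD, LAC, ImageVolume, LabelVolume, VoxelGrid
from .errors import ConfigError, GeometryError, RegionLookupError, ValidationError

MU_WATER_511 = 0.096  # cm^-1, water at 511 keV

CTAC = "ctac"
DIXON = "dixon"
DIXONBONE = "dixonbone"
UTE = "ute"
DL_DIXON = "dl_dixon"
MRAC_METHODS = (DIXON, DIXONBONE, UTE, DL_DIXON)


@dataclass(frozen=True)
class BilinearParams:
    """Two-segment HU -> 511 keV LAC model.

    Below ``break_hu`` the segment is anchored at (-1000 HU -> 0) and
    (0 HU -> mu_water); above it the bone segment continues with
    ``bone_slope_per_hu``.  The slopes are configuration: vendors use
    kVp-specific constants that are not standardized.
    """

    break_hu: float = 0.0
    mu_water: float = MU_WATER_511
    bone_slope_per_hu: float = 5.1e-5  # cm^-1 per HU, typical 120 kVp value
    max_lac: float = 0.3

    @property
    def soft_slope_per_hu(self) -> float:
        return self.mu_water / 1000.0


@dataclass(frozen=True)
class TissueLUT:
    """Tissue-class name -> 511 keV LAC (cm^-1) lookup for segmented maps."""

    entries: Mapping[str, float] = field(
        default_factory=lambda: {
            "air": 0.0,
            "fat": 0.0864,
            "soft": MU_WATER_511,
            "spongeous_bone": 0.11,
            "cortical_bone": 0.151,
        }
    )

    def __post_init__(self) -> None:
        for need in ("air", "fat", "soft"):
            if need not in self.entries:
                raise ConfigError(f"TissueLUT is missing required class {need!r}")
        if any(v < 0 for v in self.entries.values()):
            raise ConfigError("TissueLUT LAC values must be >= 0")


@dataclass(frozen=True)
class DegradeConfig:
    """Parameters of the four MRAC emulations (see module docstring)."""

    soft_lac: float = MU_WATER_511
    bone_scale: float = 0.9          # dixonbone global bone LAC bias
    bone_erosion_mm: float = 1.0     # dixonbone outer-table under-segmentation
    ute_bone_lac: float = 0.12       # single conservative binary bone LAC
    misclass_frac: float = 0.05      # ute boundary misclassification fraction
    dl_noise_sigma: float = 0.002    # dl_dixon voxelwise LAC noise, cm^-1

    def __post_init__(self) -> None:
        for name in ("misclass_frac",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.bone_scale <= 1.0:
            raise ConfigError(f"bone_scale must be in [0, 1], got {self.bone_scale}")
        if self.bone_erosion_mm < 0 or self.dl_noise_sigma < 0:
            raise ConfigError("bone_erosion_mm and dl_noise_sigma must be >= 0")


@dataclass
class MuMap:
    """A 511 keV LAC volume tagged with the attenuation-map method."""

    image: ImageVolume
    method: str

    def __post_init__(self) -> None:
        if self.image.quantity != LAC:
            raise ValidationError("MuMap image must carry lac quantity")
        if self.method not in (CTAC,) + MRAC_METHODS:
            raise ValidationError(f"unknown attenuation method {self.method!r}")
        if self.image.values.max(initial=0.0) > 0.3 + 1e-12:
            raise ValidationError("LAC values above 0.3 cm^-1 are not physical here")

    @property
    def grid(self) -> VoxelGrid:
        return self.image.grid


@dataclass
class MRACFamily:
    """The CT reference map plus the four MR-derived candidate maps."""

    reference: MuMap
    candidates: dict[str, MuMap]

    def __post_init__(self) -> None:
        if self.reference.method != CTAC:
            raise ValidationError("family reference must be the ctac map")
        if set(self.candidates) != set(MRAC_METHODS):
            raise ValidationError(
                f"candidates must be exactly {MRAC_METHODS}, got {sorted(self.candidates)}"
            )
        for m in self.candidates.values():
            self.reference.grid.require_same(m.grid, "attenuation maps")

    def all_maps(self) -> dict[str, MuMap]:
        out = {CTAC: self.reference}
        out.update(self.candidates)
        return out


def hu_to_lac(ct: ImageVolume, params: BilinearParams | None = None) -> ImageVolume:
    """Bilinear Hounsfield -> 511 keV LAC conversion, clipped to [0, max_lac].

    Continuous at the break point: the soft segment runs through the air and
    water anchors, the bone segment continues from the break with its own
    slope.
    """
    if ct.quantity != HOUNSFIELD:
        raise TypeError(f"hu_to_lac expects a hounsfield volume, got {ct.quantity}")
    p = params or BilinearParams()
    hu = ct.values
    soft = p.mu_water + p.soft_slope_per_hu * hu
    mu_break = p.mu_water + p.soft_slope_per_hu * p.break_hu
    bone = mu_break + p.bone_slope_per_hu * (hu - p.break_hu)
    mu = np.where(hu <= p.break_hu, soft, bone)
    mu = np.clip(mu, 0.0, p.max_lac)
    return ImageVolume(ct.grid, mu, LAC)


def classes_to_mu(classmap: LabelVolume, lut: TissueLUT,
                  class_names: Mapping[int, str] | None = None) -> MuMap:
    """Segmented tissue-class map -> LAC volume by LUT lookup.

    ``class_names`` defaults to the classmap's own name table; background
    (label 0) maps to the air LAC.
    """
    names = dict(class_names or classmap.name_table)
    out = np.full(classmap.grid.shape, lut.entries["air"], dtype=float)
    for label in classmap.region_ids:
        name = names.get(label)
        if name is None or name not in lut.entries:
            raise RegionLookupError(
                f"tissue class for label {label} ({name!r}) has no LUT entry"
            )
        out[classmap.labels == label] = lut.entries[name]
    return MuMap(ImageVolume(classmap.grid, out, LAC), DIXON)


def resample_nearest(src: ImageVolume, target: VoxelGrid) -> ImageVolume:
    """Nearest-neighbour resampling onto ``target`` in world coordinates.

    Each target voxel takes the value of the src voxel whose center is
    nearest; target voxels outside the src extent take the quantity's fill
    value (0, or -1000 for HU).
    """
    lo = np.array(src.grid.origin_mm) - 0.5 * np.array(src.grid.voxel_size_mm)
    hi = lo + np.array(src.grid.shape) * np.array(src.grid.voxel_size_mm)
    tlo = np.array(target.origin_mm) - 0.5 * np.array(target.voxel_size_mm)
    thi = tlo + np.array(target.shape) * np.array(target.voxel_size_mm)
    if np.any(thi <= lo) or np.any(tlo >= hi):
        raise GeometryError("source and target grids are disjoint in world space")

    fill = -1000.0 if src.quantity == HOUNSFIELD else 0.0
    idx = []
    inside = np.ones(target.shape, dtype=bool)
    for a in range(3):
        coords = target.voxel_centers(a)
        i = np.rint((coords - src.grid.origin_mm[a]) / src.grid.voxel_size_mm[a])
        ok = (i >= 0) & (i < src.grid.shape[a])
        i = np.clip(i, 0, src.grid.shape[a] - 1).astype(np.int64)
        idx.append(i)
        shape = [1, 1, 1]
        shape[a] = -1
        inside &= ok.reshape(shape)
    out = src.values[np.ix_(idx[0], idx[1], idx[2])].copy()
    out[~inside] = fill
    return ImageVolume(target, out, src.quantity)


def _peel_outer(mask: np.ndarray, grid: VoxelGrid, distance_mm: float) -> np.ndarray:
    """Remove the outer ``distance_mm`` of a closed shell, keeping its inner side.

    A plain erosion would eat a thin shell from both faces and destroy it;
    model-based bone segmentation errs on the *outer* table, so the shell is
    filled per axial slice, the filled solid is eroded, and the shell is
    intersected with it.
    """
    n = int(round(distance_mm / min(grid.voxel_size_mm[:2])))
    if distance_mm <= 0 or n == 0:
        return mask
    filled = np.stack(
        [ndi.binary_fill_holes(mask[:, :, k]) for k in range(mask.shape[2])], axis=2
    )
    struct = ndi.generate_binary_structure(3, 1).copy()
    struct[:, :, 0] = struct[:, :, 2] = False  # erode in-plane only
    eroded = ndi.binary_erosion(filled, structure=struct, iterations=n, border_value=0)
    return mask & eroded


def derive_mrac_family(bundle, degrade: DegradeConfig | None = None,
                       seed: int = 0) -> MRACFamily:
    """Build the CTAC reference and the four MRAC emulations for a phantom.

    Only the skull shell (and, for ``ute``, the scalp voxels touching it) is
    modified by the segmentation-based methods; ``dl_dixon`` adds voxelwise
    noise everywhere, emulating a pseudo-CT network's residual error.
    """
    degrade = degrade or DegradeConfig()
    rng = np.random.default_rng(seed)
    mu_true = bundle.mu_true
    grid = mu_true.grid
    skull = bundle.atlas.mask(bundle.atlas.id_of("skull"))

    def as_map(values: np.ndarray, method: str) -> MuMap:
        return MuMap(ImageVolume(grid, np.clip(values, 0.0, 0.3), LAC), method)

    reference = MuMap(ImageVolume(grid, mu_true.values.copy(), LAC), CTAC)

    # DIXON: bone invisible -> skull becomes uniform soft tissue
    dixon = mu_true.values.copy()
    dixon[skull] = degrade.soft_lac

    # DIXONbone: continuous bone LAC, globally biased and outer-table-eroded
    kept = _peel_outer(skull, grid, degrade.bone_erosion_mm)
    dixonbone = mu_true.values.copy()
    dixonbone[skull] = degrade.soft_lac
    dixonbone[kept] = degrade.bone_scale * mu_true.values[kept]

    # UTE: binary bone compartment at one fixed LAC + boundary misclassification
    ute = mu_true.values.copy()
    ute[skull] = degrade.ute_bone_lac
    inner = ndi.binary_erosion(skull, border_value=0)
    bone_boundary = skull & ~inner
    # scalp voxels touching the skull (outside it, non-air) may be called bone;
    # the brain side is left untouched
    dilated = ndi.binary_dilation(skull, border_value=0)
    scalp_boundary = dilated & ~skull & (mu_true.values > 0.5 * degrade.soft_lac) \
        & (bundle.atlas.labels == bundle.atlas.id_of("scalp"))
    for bmask, new_val in ((bone_boundary, degrade.soft_lac),
                           (scalp_boundary, degrade.ute_bone_lac)):
        n = int(bmask.sum())
        if n == 0:
            continue
        pick = rng.random(n) < degrade.misclass_frac
        flat = np.flatnonzero(bmask)
        ute.flat[flat[pick]] = new_val

    # DL-DIXON: near-truth pseudo-CT with small voxelwise noise
    dl = mu_true.values + rng.normal(0.0, degrade.dl_noise_sigma, grid.shape)

    return MRACFamily(
        reference=reference,
        candidates={
            DIXON: as_map(dixon, DIXON),
            DIXONBONE: as_map(dixonbone, DIXONBONE),
            UTE: as_map(ute, UTE),
            DL_DIXON: as_map(dl, DL_DIXON),
        },
    )
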