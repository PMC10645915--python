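"""Voxel grids and scalar image volumes.

These are the in-memory containers the whole pipeline passes around: a
:class:`VoxelGrid` fixes the sampling (shape, voxel size, world origin) and
an :class:`ImageVolume` couples a grid with a scalar field and a physical
quantity tag (activity in Bq/mL, CT numbers in HU, 511 keV linear
attenuation coefficients in cm^-1, or a unitless label probability).
Grids must match exactly for two volumes to be combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import GeometryError, ValidationError

#: Recognized quantity tags for ImageVolume.
ACTIVITY = "activity"
HOUNSFIELD = "hounsfield"
LAC = "lac"
LABEL_PROB = "label-probability"

_QUANTITIES = frozenset({ACTIVITY, HOUNSFIELD, LAC, LABEL_PROB})


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel lattice in world (mm) coordinates.

    ``origin_mm`` is the world coordinate of the *center* of voxel (0, 0, 0);
    voxel (i, j, k) is centered at ``origin_mm + (i, j, k) * voxel_size_mm``.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        object.__setattr__(
            self, "origin_mm", tuple(float(v) for v in self.origin_mm)
        )
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise GeometryError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise GeometryError(
                f"voxel sizes must be positive, got {self.voxel_size_mm}"
            )

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int],
        voxel_size_mm: tuple[float, float, float],
    ) -> "VoxelGrid":
        """Grid whose world origin sits at the geometric center of the volume."""
        origin = tuple(
            -(n - 1) / 2.0 * v for n, v in zip(shape, voxel_size_mm)
        )
        return cls(tuple(shape), tuple(voxel_size_mm), origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + np.arange(n) * self.voxel_size_mm[axis]

    def meshgrid_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate meshgrid (ij indexing), one array per axis."""
        xs = [self.voxel_centers(a) for a in range(3)]
        return tuple(np.meshgrid(*xs, indexing="ij"))

    def same_as(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def require_same(self, other: "VoxelGrid", what: str = "volumes") -> None:
        if not self.same_as(other):
            raise GeometryError(f"{what} are on different grids: {self} vs {other}")


@dataclass
class ImageVolume:
    """Scalar field on a :class:`VoxelGrid` with a physical quantity tag."""

    grid: VoxelGrid
    values: np.ndarray
    quantity: str = ACTIVITY

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.quantity not in _QUANTITIES:
            raise ValidationError(f"unknown quantity {self.quantity!r}")
        if self.values.shape != self.grid.shape:
            raise GeometryError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.quantity in (ACTIVITY, LAC, LABEL_PROB) and np.any(self.values < 0):
            raise ValidationError(f"{self.quantity} volume has negative voxels")
        if self.quantity == HOUNSFIELD and np.any(self.values < -1024):
            raise ValidationError("HU volume has voxels below -1024")

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.grid, self.values.copy(), self.quantity)

    def with_values(self, values: np.ndarray, quantity: str | None = None) -> "ImageVolume":
        return ImageVolume(self.grid, values, quantity or self.quantity)


@dataclass
class LabelVolume:
    """Integer region atlas on a grid; label 0 is reserved for background."""

    grid: VoxelGrid
    labels: np.ndarray
    name_table: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label array must be integer-typed")
        if self.labels.shape != self.grid.shape:
            raise GeometryError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        if self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(int(k) for k in self.name_table)
        if missing:
            raise ValidationError(f"labels without names: {sorted(missing)}")

    @property
    def region_ids(self) -> list[int]:
        """Sorted non-zero labels present in the volume."""
        return sorted(set(np.unique(self.labels).tolist()) - {0})

    def id_of(self, name: str) -> int:
        for k, v in self.name_table.items():
            if v == name:
                return int(k)
        raise KeyError(name)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label
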