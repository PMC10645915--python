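"""Multi-slice parallel-beam tomographic model.

The scanner is modelled as a stack of independent 2-D parallel-beam
sinograms (one per image slice): rays at ``n_angles`` uniformly spaced view
angles in [0, pi) and ``n_radial`` signed radial offsets centered on the
image grid.  Each (radial, angle) bin corresponds to one ray traced through
the in-plane voxel lattice with an exact Siddon-style traversal, so every
bin value is the true line integral sum(value_i * length_i) in value*mm.

Because the ray weights for a (grid, geometry) pair never change, they are
assembled once into a sparse matrix ``A`` of shape (n_radial*n_angles,
nx*ny) and cached; forward projection is ``A @ x`` applied to all slices at
once and back projection is the exact adjoint ``A.T @ y``.  This makes the
forward/back pair adjoint to machine precision by construction, which the
EM reconstruction relies on.

Angle convention: theta = 0 rays run parallel to the y axis; the ray for
radial offset s at angle theta passes through ``center + s*(cos t, sin t)``
with direction ``(-sin t, cos t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp

from .core import ImageVolume, VoxelGrid, ACTIVITY, LAC
from .errors import GeometryError, ValidationError

LINE_INTEGRAL = "line-integral"
EXPECTED_COUNTS = "expected-counts"
COUNTS = "counts"
FACTORS = "factors"
_CONTENTS = frozenset({LINE_INTEGRAL, EXPECTED_COUNTS, COUNTS, FACTORS})


@dataclass(frozen=True)
class SinogramGeometry:
    """Sampling of projection space: radial bins x view angles x slices."""

    n_radial: int
    n_angles: int
    n_slices: int
    radial_bin_mm: float

    def __post_init__(self) -> None:
        if min(self.n_radial, self.n_angles, self.n_slices) < 1:
            raise GeometryError("sinogram dimensions must all be >= 1")
        if self.radial_bin_mm <= 0:
            raise GeometryError("radial_bin_mm must be positive")

    @property
    def angles(self) -> np.ndarray:
        """View angles, uniform over [0, pi)."""
        return np.arange(self.n_angles) * (math.pi / self.n_angles)

    @property
    def radial_offsets_mm(self) -> np.ndarray:
        """Signed radial bin centers, symmetric about 0."""
        return (np.arange(self.n_radial) - (self.n_radial - 1) / 2.0) * self.radial_bin_mm

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_radial, self.n_angles, self.n_slices)


def default_geometry(grid: VoxelGrid, n_angles: int | None = None) -> SinogramGeometry:
    """Geometry covering ``grid``: 1.5*nx radial bins of one voxel pitch."""
    nx = grid.shape[0]
    if n_angles is None:
        n_angles = max(nx, 96)
    return SinogramGeometry(
        n_radial=int(math.ceil(1.5 * nx)),
        n_angles=int(n_angles),
        n_slices=grid.shape[2],
        radial_bin_mm=float(grid.voxel_size_mm[0]),
    )


@dataclass
class Sinogram:
    """Projection-space array with a content tag.

    ``values`` has shape (n_radial, n_angles, n_slices) and is non-negative
    for every content kind; ``factors`` content is additionally <= 1.
    """

    geometry: SinogramGeometry
    values: np.ndarray
    content: str = LINE_INTEGRAL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.content not in _CONTENTS:
            raise ValidationError(f"unknown sinogram content {self.content!r}")
        if self.values.shape != self.geometry.shape:
            raise GeometryError(
                f"sinogram shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        if np.any(self.values < 0):
            raise ValidationError(f"{self.content} sinogram has negative bins")
        if self.content == FACTORS and np.any(self.values > 1.0 + 1e-12):
            raise ValidationError("factor sinogram has bins > 1")

    def copy(self) -> "Sinogram":
        return Sinogram(self.geometry, self.values.copy(), self.content)


@dataclass(frozen=True)
class PSFModel:
    """Isotropic Gaussian point-spread function, FWHM in mm."""

    fwhm_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValidationError("PSF fwhm_mm must be positive")

    @property
    def sigma_mm(self) -> float:
        return self.fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# --------------------------------------------------------------------------
# system matrix

_MATRIX_CACHE: dict[tuple, sp.csr_matrix] = {}


def _grid_key(grid: VoxelGrid) -> tuple:
    return (grid.shape[:2], grid.voxel_size_mm[:2], grid.origin_mm[:2])


def _siddon_matrix(grid: VoxelGrid, geom: SinogramGeometry) -> sp.csr_matrix:
    """Exact intersection-length matrix, rows ordered (radial, angle) C-style."""
    nx, ny = grid.shape[0], grid.shape[1]
    vx, vy = grid.voxel_size_mm[0], grid.voxel_size_mm[1]
    x0 = grid.origin_mm[0] - 0.5 * vx  # first x voxel edge
    y0 = grid.origin_mm[1] - 0.5 * vy
    x_edges = x0 + np.arange(nx + 1) * vx
    y_edges = y0 + np.arange(ny + 1) * vy
    # in-plane grid center; radial coordinate is measured from here
    cx = grid.origin_mm[0] + (nx - 1) / 2.0 * vx
    cy = grid.origin_mm[1] + (ny - 1) / 2.0 * vy

    angles = geom.angles
    offsets = geom.radial_offsets_mm

    rows_parts, cols_parts, data_parts = [], [], []
    # chunk over angles to bound the sort workspace
    chunk = max(1, int(4_000_000 // (geom.n_radial * (nx + ny + 4))) or 1)
    for a0 in range(0, geom.n_angles, chunk):
        ang = angles[a0 : a0 + chunk]
        na = ang.size
        ct, st = np.cos(ang), np.sin(ang)
        # ray base points and directions, shape (n_radial, na)
        p0x = cx + offsets[:, None] * ct[None, :]
        p0y = cy + offsets[:, None] * st[None, :]
        dx = np.broadcast_to(-st, (geom.n_radial, na))
        dy = np.broadcast_to(ct, (geom.n_radial, na))

        R = geom.n_radial * na
        p0x, p0y = p0x.reshape(R), p0y.reshape(R)
        dx, dy = dx.reshape(R).copy(), dy.reshape(R).copy()

        with np.errstate(divide="ignore", invalid="ignore"):
            tx = (x_edges[None, :] - p0x[:, None]) / dx[:, None]
            ty = (y_edges[None, :] - p0y[:, None]) / dy[:, None]
        # rays parallel to an axis never cross that axis' planes
        tx[np.abs(dx) < 1e-12, :] = np.inf
        ty[np.abs(dy) < 1e-12, :] = np.inf
        tx = np.nan_to_num(tx, nan=np.inf, posinf=np.inf, neginf=-np.inf)
        ty = np.nan_to_num(ty, nan=np.inf, posinf=np.inf, neginf=-np.inf)

        def slab(p0, d, lo, hi):
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = (lo - p0) / d
                t2 = (hi - p0) / d
            tmin = np.minimum(t1, t2)
            tmax = np.maximum(t1, t2)
            par = np.abs(d) < 1e-12
            inside = (p0 > lo) & (p0 < hi)
            tmin = np.where(par, np.where(inside, -np.inf, np.inf), tmin)
            tmax = np.where(par, np.where(inside, np.inf, -np.inf), tmax)
            return tmin, tmax

        txmin, txmax = slab(p0x, dx, x_edges[0], x_edges[-1])
        tymin, tymax = slab(p0y, dy, y_edges[0], y_edges[-1])
        tmin = np.maximum(txmin, tymin)
        tmax = np.minimum(txmax, tymax)
        hit = tmax > tmin
        # rays that miss the grid get a degenerate [0, 0] window -> no segments
        tmin = np.where(hit, tmin, 0.0)
        tmax = np.where(hit, tmax, 0.0)

        ts = np.concatenate([tx, ty, tmin[:, None], tmax[:, None]], axis=1)
        ts = np.clip(ts, tmin[:, None], tmax[:, None])
        ts = np.where(np.isfinite(ts), ts, tmax[:, None])
        ts.sort(axis=1)
        seg = np.diff(ts, axis=1)  # |d| = 1 so dt is length in mm
        tm = 0.5 * (ts[:, :-1] + ts[:, 1:])
        mx = p0x[:, None] + tm * dx[:, None]
        my = p0y[:, None] + tm * dy[:, None]
        ix = np.floor((mx - x0) / vx).astype(np.int64)
        iy = np.floor((my - y0) / vy).astype(np.int64)
        ok = (
            (seg > 1e-9)
            & hit[:, None]
            & (ix >= 0)
            & (ix < nx)
            & (iy >= 0)
            & (iy < ny)
        )
        ray_idx = np.broadcast_to(np.arange(R)[:, None], seg.shape)
        rows = ray_idx[ok]
        cols = (ix[ok] * ny + iy[ok]).astype(np.int64)
        data = seg[ok]
        # translate chunk-local ray index (radial-major over this angle block)
        # to global (radial, angle) C-order row index
        irad, iang = np.divmod(rows, na)
        rows_parts.append(irad * geom.n_angles + (a0 + iang))
        cols_parts.append(cols)
        data_parts.append(data)

    mat = sp.coo_matrix(
        (
            np.concatenate(data_parts),
            (np.concatenate(rows_parts), np.concatenate(cols_parts)),
        ),
        shape=(geom.n_radial * geom.n_angles, nx * ny),
    )
    mat.sum_duplicates()
    return mat.tocsr()


def system_matrix(grid: VoxelGrid, geom: SinogramGeometry) -> sp.csr_matrix:
    """Cached sparse projector for the in-plane (grid, geometry) pair."""
    key = (
        _grid_key(grid),
        geom.n_radial,
        geom.n_angles,
        geom.radial_bin_mm,
    )
    if key not in _MATRIX_CACHE:
        _MATRIX_CACHE[key] = _siddon_matrix(grid, geom)
    return _MATRIX_CACHE[key]


def _check_compat(grid: VoxelGrid, geom: SinogramGeometry) -> None:
    if grid.shape[2] != geom.n_slices:
        raise GeometryError(
            f"grid has {grid.shape[2]} slices but geometry expects {geom.n_slices}"
        )
    extent = math.hypot(
        grid.shape[0] * grid.voxel_size_mm[0], grid.shape[1] * grid.voxel_size_mm[1]
    )
    if geom.n_radial * geom.radial_bin_mm < extent - 1e-9:
        raise GeometryError(
            "radial extent does not cover the image diagonal: "
            f"{geom.n_radial * geom.radial_bin_mm:.1f} mm < {extent:.1f} mm"
        )


def forward_project(img: ImageVolume, geom: SinogramGeometry) -> Sinogram:
    """Line integrals (value*mm) of ``img`` along every sinogram ray."""
    _check_compat(img.grid, geom)
    A = system_matrix(img.grid, geom)
    nz = img.grid.shape[2]
    x2d = img.values.reshape(-1, nz)
    y = A @ x2d
    vals = y.reshape(geom.n_radial, geom.n_angles, nz)
    return Sinogram(geom, np.maximum(vals, 0.0), LINE_INTEGRAL)


def back_project(sino: Sinogram, grid: VoxelGrid) -> ImageVolume:
    """Exact adjoint of :func:`forward_project` (transposed ray weights)."""
    _check_compat(grid, sino.geometry)
    A = system_matrix(grid, sino.geometry)
    nz = grid.shape[2]
    y2d = sino.values.reshape(-1, nz)
    x = A.T @ y2d
    return ImageVolume(grid, np.maximum(x, 0.0).reshape(grid.shape), ACTIVITY)


def attenuation_factors(mu: "ImageVolume | object", geom: SinogramGeometry) -> Sinogram:
    """Survival probabilities exp(-integral mu dl) per bin, in (0, 1].

    ``mu`` is a LAC volume in cm^-1 (or a MuMap wrapping one); traced path
    lengths are in mm and converted to cm inside the exponent.
    """
    img = getattr(mu, "image", mu)
    if img.quantity != LAC:
        raise ValidationError(f"attenuation_factors needs a lac volume, got {img.quantity}")
    if np.any(img.values < 0):
        raise ValidationError("negative linear attenuation coefficients")
    li = forward_project(img, geom)  # cm^-1 * mm
    return Sinogram(geom, np.exp(-li.values / 10.0), FACTORS)


def apply_psf(img: ImageVolume, psf: PSFModel | None) -> ImageVolume:
    """Image-space Gaussian blur emulating the scanner point-spread function.

    Edge effects are renormalized (division by the blurred indicator of the
    field of view) and the total sum is restored exactly, so activity is
    conserved.  A FWHM below half the smallest voxel is the identity.
    """
    if psf is None:
        return img.copy()
    vox = img.grid.voxel_size_mm
    if psf.fwhm_mm < 0.5 * min(vox):
        return img.copy()
    sigma_vox = [psf.sigma_mm / v for v in vox]
    blurred = ndi.gaussian_filter(img.values, sigma_vox, mode="constant")
    norm = ndi.gaussian_filter(np.ones_like(img.values), sigma_vox, mode="constant")
    out = blurred / norm
    total_in = img.values.sum()
    total_out = out.sum()
    if total_out > 0:
        out *= total_in / total_out
    return img.with_values(np.maximum(out, 0.0))
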