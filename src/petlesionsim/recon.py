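"""Attenuation- and normalization-corrected OSEM reconstruction.

Ordered-subsets expectation maximization with the standard multiplicative
update.  The system model per bin is

    expected = a * n * c * (P x) + s

with ``a`` the attenuation factors of the chosen attenuation map, ``n`` the
normalization factors, ``c = sensitivity * duration`` the calibration
constant, ``P`` the line-integral projector and ``s`` the known additive
scatter expectation.  Because ``c`` is folded into the factors, the iterate
``x`` is directly in activity units (Bq/mL).  Subsets partition the view
angles by interleaving (angle i -> subset i mod n_subsets); one subset is
plain MLEM, whose likelihood monotonicity is used as a correctness check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ACTIVITY, ImageVolume, VoxelGrid
from .errors import ConfigError, GeometryError
from .mumaps import MRACFamily, MuMap
from .insertion import AcquisitionModel
from .projector import (
    PSFModel,
    Sinogram,
    SinogramGeometry,
    apply_psf,
    attenuation_factors,
    system_matrix,
)


@dataclass(frozen=True)
class ReconConfig:
    """OSEM iteration controls and post-filter."""

    n_iterations: int = 3
    n_subsets: int = 21
    post_filter_fwhm_mm: float = 4.0
    epsilon: float = 1e-12
    init_value: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_subsets < 1:
            raise ConfigError("n_iterations and n_subsets must be >= 1")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")
        if self.post_filter_fwhm_mm < 0:
            raise ConfigError("post_filter_fwhm_mm must be >= 0")


@dataclass
class ReconResult:
    """Reconstructed activity image plus the settings that produced it."""

    image: ImageVolume
    config: ReconConfig
    mu_method: str


def _subset_rows(geom: SinogramGeometry, n_subsets: int) -> list[np.ndarray]:
    if n_subsets > geom.n_angles:
        raise ConfigError(
            f"{n_subsets} subsets for {geom.n_angles} angles leaves empty subsets"
        )
    base = np.arange(geom.n_radial) * geom.n_angles
    rows = []
    for s in range(n_subsets):
        angles = np.arange(s, geom.n_angles, n_subsets)
        rows.append(np.add.outer(base, angles).ravel())
    return rows


def poisson_loglik(
    counts: Sinogram,
    image: ImageVolume,
    mu: MuMap,
    acq: AcquisitionModel,
    scatter: Optional[Sinogram],
    eps: float = 1e-12,
) -> float:
    """Poisson log-likelihood of the data under the OSEM system model."""
    geom = counts.geometry
    A = system_matrix(image.grid, geom)
    nz = image.grid.shape[2]
    f = (
        attenuation_factors(mu, geom).values
        * acq.norm_values(geom)
        * acq.sensitivity
        * acq.duration_s
    )
    ybar = f * (A @ image.values.reshape(-1, nz)).reshape(geom.shape)
    if scatter is not None:
        ybar = ybar + scatter.values
    y = counts.values
    return float(np.sum(y * np.log(ybar + eps) - ybar))


def osem_reconstruct(
    counts: Sinogram,
    mu: MuMap,
    acq: AcquisitionModel,
    scatter: Optional[Sinogram],
    geom: SinogramGeometry,
    cfg: ReconConfig | None = None,
    init: Optional[ImageVolume] = None,
) -> ReconResult:
    """OSEM reconstruction of a count sinogram under the given attenuation map."""
    cfg = cfg or ReconConfig()
    grid = mu.grid
    if counts.geometry.shape != geom.shape:
        raise GeometryError("counts sinogram does not match the requested geometry")
    nz = grid.shape[2]
    nvox = grid.shape[0] * grid.shape[1]

    A = system_matrix(grid, geom)
    factors = (
        attenuation_factors(mu, geom).values
        * acq.norm_values(geom)
        * acq.sensitivity
        * acq.duration_s
    ).reshape(-1, nz)
    y = counts.values.reshape(-1, nz).astype(float)
    s = (
        scatter.values.reshape(-1, nz)
        if scatter is not None
        else np.zeros_like(y)
    )

    rows_per_subset = _subset_rows(geom, cfg.n_subsets)
    subs = []
    for rows in rows_per_subset:
        A_s = A[rows]
        f_s = factors[rows]
        sens = A_s.T @ f_s  # per-voxel sensitivity of this subset
        subs.append((A_s, f_s, y[rows], s[rows], sens))

    if init is not None:
        grid.require_same(init.grid, "init image and attenuation map")
        x = init.values.reshape(nvox, nz).astype(float).copy()
    else:
        x = np.full((nvox, nz), float(cfg.init_value))
    total_sens = sum(sub[4] for sub in subs)
    x[total_sens <= 0] = 0.0  # voxels unseen by any ray are frozen at 0
    eps = cfg.epsilon
    for _ in range(cfg.n_iterations):
        for A_s, f_s, y_s, s_s, sens in subs:
            ybar = f_s * (A_s @ x) + s_s
            ratio = f_s * y_s / (ybar + eps)
            back = A_s.T @ ratio
            # voxels this subset cannot see keep their value (update = 1)
            upd = np.divide(back, sens, out=np.ones_like(back), where=sens > 0)
            x *= upd

    img = ImageVolume(grid, np.maximum(x, 0.0).reshape(grid.shape), ACTIVITY)
    if cfg.post_filter_fwhm_mm > 0:
        img = apply_psf(img, PSFModel(cfg.post_filter_fwhm_mm))
    return ReconResult(image=img, config=cfg, mu_method=mu.method)


def reconstruct_all(
    counts: Sinogram,
    family: MRACFamily,
    acq: AcquisitionModel,
    scatter: Optional[Sinogram],
    geom: SinogramGeometry,
    cfg: ReconConfig | None = None,
) -> dict[str, ReconResult]:
    """Reconstruct one count sinogram under all five attenuation maps.

    The data are identical across entries; only the attenuation factors in
    the system model differ, so image differences isolate the AC method.
    """
    out = {}
    for method, mumap in family.all_maps().items():
        out[method] = osem_reconstruct(counts, mumap, acq, scatter, geom, cfg)
    return out
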