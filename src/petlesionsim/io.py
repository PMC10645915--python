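"""NIfTI-1 and sidecar I/O.

Volumes are stored as NIfTI-1 with a diagonal affine carrying the voxel
size and the world coordinate of voxel (0,0,0); label atlases get a JSON
sidecar with the label->name table, sinograms a JSON sidecar with their
geometry.  Values round-trip exactly (float64 on disk).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import ImageVolume, LabelVolume, VoxelGrid
from .errors import VolumeIOError
from .projector import Sinogram, SinogramGeometry


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.voxel_size_mm) + [1.0])
    aff[:3, 3] = grid.origin_mm
    return aff


def _grid_from(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    voxel = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(3))
    origin = tuple(float(v) for v in aff[:3, 3])
    return VoxelGrid(tuple(int(n) for n in img.shape[:3]), voxel, origin)


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.values.astype(np.float64), _affine(vol.grid))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, quantity: str = "activity") -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeIOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return ImageVolume(_grid_from(img), np.asanyarray(img.dataobj, dtype=float), quantity)


def write_atlas(atlas: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), _affine(atlas.grid))
    nib.save(img, str(path))
    sidecar = path.with_name(path.name.split(".")[0] + "_labels.json")
    sidecar.write_text(
        json.dumps({str(k): v for k, v in atlas.name_table.items()},
                   indent=2, sort_keys=True) + "\n"
    )
    return path


def read_atlas(path: str | Path) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such atlas file: {path}")
    img = nib.load(str(path))
    sidecar = path.with_name(path.name.split(".")[0] + "_labels.json")
    if not sidecar.exists():
        raise VolumeIOError(f"atlas sidecar missing: {sidecar}")
    names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    labels = np.asanyarray(img.dataobj).astype(np.int64)
    return LabelVolume(_grid_from(img), labels, names)


def write_sinogram(sino: Sinogram, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(sino.values.astype(np.float64), np.eye(4))
    nib.save(img, str(path))
    g = sino.geometry
    sidecar = path.with_name(path.name.split(".")[0] + "_geometry.json")
    sidecar.write_text(
        json.dumps(
            {
                "n_radial": g.n_radial,
                "n_angles": g.n_angles,
                "n_slices": g.n_slices,
                "radial_bin_mm": g.radial_bin_mm,
                "content": sino.content,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return path


def read_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such sinogram file: {path}")
    sidecar = path.with_name(path.name.split(".")[0] + "_geometry.json")
    if not sidecar.exists():
        raise VolumeIOError(f"sinogram sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    geom = SinogramGeometry(
        n_radial=meta["n_radial"],
        n_angles=meta["n_angles"],
        n_slices=meta["n_slices"],
        radial_bin_mm=meta["radial_bin_mm"],
    )
    values = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    if meta["content"] == "counts":
        values = values.astype(np.int64)
    return Sinogram(geom, values, meta["content"])
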