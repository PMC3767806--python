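"""Reading, writing and regridding of 3D white-matter volumes.

The pipeline's universal containers live here:

* :class:`ProbabilityVolume` — a scalar field in [0, 1], typically a
  white-matter tissue-probability map produced by a segmentation tool.
* :class:`VoxelGrid` — a binary occupancy grid (mask, skeleton, surface,
  hemisphere piece) on the same kind of grid.

Both carry the NIfTI affine so spatial metadata survives a round trip.
All downstream morphology and box counting assume cubic voxels, so
anisotropic inputs pass through :func:`resample_isotropic` first.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: The nine fractal-dimension outcomes: 3 shape features x {left, right, whole}.
FD_COLUMNS = [
    f"fd_{feature}_{hemi}"
    for feature in ("skeleton", "surface", "general")
    for hemi in ("lh", "rh", "wb")
]

#: Fixed column order of the cohort FD report.
REPORT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "gender",
    "alsfrs_r",
    "duration_months",
    "ees",
] + FD_COLUMNS


class VolumeError(ValueError):
    """Raised for volumes that violate the pipeline's grid contracts."""


def _check_3d(data: np.ndarray) -> np.ndarray:
    """Squeeze trailing singleton axes; reject anything not reducible to 3D."""
    arr = np.asarray(data)
    while arr.ndim > 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise VolumeError(
            f"expected a 3D volume, got shape {np.asarray(data).shape} "
            "(non-squeezable extra axes)"
        )
    if any(s < 1 for s in arr.shape):
        raise VolumeError(f"every axis must have length >= 1, got {arr.shape}")
    return arr


def _voxel_size_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(affine, dtype=float)[:3, :3], axis=0)


@dataclasses.dataclass
class ProbabilityVolume:
    """A 3D scalar field in [0, 1] with voxel-size metadata.

    Parameters
    ----------
    data:
        3D float array; values outside [0, 1] by more than 1e-6 are an error.
    affine:
        4x4 voxel-to-world matrix (NIfTI convention). Voxel sizes are the
        column norms of its 3x3 block.
    """

    data: np.ndarray
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.data = _check_3d(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeError(f"affine must be 4x4, got {self.affine.shape}")
        n_nan = int(np.isnan(self.data).sum())
        if n_nan:
            raise VolumeError(f"volume contains {n_nan} NaN voxel(s)")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise VolumeError(
                f"probability values must lie in [0, 1]; found range "
                f"[{lo:.6g}, {hi:.6g}]"
            )
        # Snap harmless float fuzz back onto [0, 1].
        np.clip(self.data, 0.0, 1.0, out=self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Physical edge length per axis, in mm."""
        return _voxel_size_from_affine(self.affine)


@dataclasses.dataclass
class VoxelGrid:
    """A 3D binary occupancy grid with voxel-size metadata."""

    data: np.ndarray
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4)
    )

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        arr = _check_3d(arr)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise VolumeError(
                    f"voxel grid must be binary; found values {uniq[:10]}"
                )
            arr = arr.astype(bool)
        self.data = arr
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeError(f"affine must be 4x4, got {self.affine.shape}")
        if np.any(self.voxel_size <= 0):
            raise VolumeError(
                f"voxel sizes must be strictly positive, got {self.voxel_size}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        return _voxel_size_from_affine(self.affine)

    def count(self) -> int:
        """Number of occupied voxels."""
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """A new grid with the same metadata and different occupancy."""
        return VoxelGrid(data=data, affine=self.affine.copy())


def read_volume(path: str | Path) -> ProbabilityVolume:
    """Read a NIfTI probability volume.

    Trailing singleton axes are squeezed; genuinely 4D inputs and NaN
    voxels are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    return ProbabilityVolume(data=data, affine=np.asarray(img.affine))


def write_volume(vol: ProbabilityVolume | VoxelGrid, path: str | Path) -> None:
    """Write a probability volume or binary grid as NIfTI-1."""
    data = vol.data.astype(np.float32 if isinstance(vol, ProbabilityVolume) else np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))


def resample_isotropic(
    vol: ProbabilityVolume, target_mm: float = 1.0
) -> ProbabilityVolume:
    """Resample a probability map onto cubic voxels of edge ``target_mm``.

    Linear interpolation is used so the 0.5 level set (the binarization
    threshold downstream) is preserved better than with nearest-neighbour.
    Already-isotropic inputs at the target spacing are returned unchanged.
    The operation is idempotent at a fixed target.
    """
    if target_mm <= 0:
        raise VolumeError(f"target voxel size must be positive, got {target_mm}")
    vs = vol.voxel_size
    if np.allclose(vs, target_mm, atol=1e-9):
        return vol
    zoom = vs / float(target_mm)
    data = ndimage.zoom(vol.data, zoom, order=1, mode="nearest", grid_mode=True)
    data = np.clip(data, 0.0, 1.0)
    # Rescale the direction cosines to the new spacing; keep the origin.
    affine = vol.affine.copy()
    dirs = affine[:3, :3] / vs[np.newaxis, :]
    affine[:3, :3] = dirs * float(target_mm)
    return ProbabilityVolume(data=data, affine=affine)


def write_fd_report(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write the per-subject FD report as delimited text with a fixed header.

    All nine FD columns must be present; missing ones are reported by name.
    """
    missing = [c for c in REPORT_COLUMNS if c not in table.columns]
    if missing:
        raise VolumeError(f"FD report is missing column(s): {', '.join(missing)}")
    extra = [c for c in table.columns if c not in REPORT_COLUMNS]
    table[REPORT_COLUMNS + extra].to_csv(path, sep=sep, index=False)


def read_fd_report(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a report written by :func:`write_fd_report`."""
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in REPORT_COLUMNS if c not in table.columns]
    if missing:
        raise VolumeError(f"FD report is missing column(s): {', '.join(missing)}")
    return table
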