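"""4D BOLD series container and NIfTI-1 I/O helpers.

The in-memory unit of the whole pipeline is :class:`BoldSeries`: a 4D
``(x, y, z, t)`` array together with its repetition time and affine.
All temporal operations act on the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["BoldSeries", "load_bold", "save_bold", "save_volume", "load_volume"]


def default_affine(voxel_size_mm: float) -> np.ndarray:
    """RAS affine with isotropic voxels centered at the origin corner."""
    aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return aff


@dataclass
class BoldSeries:
    """A subject's 4D BOLD run.

    Parameters
    ----------
    data
        Array of shape ``(x, y, z, t)``; finite values.
    tr
        Repetition time in seconds.
    affine
        4x4 voxel-to-world affine (mm).
    mask
        Optional boolean validity mask on the 3D grid.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x,y,z,t); got shape {self.data.shape}")
        if self.data.shape[-1] < 2:
            raise ValueError("BOLD series needs at least 2 timepoints")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid_shape:
                raise ValueError("mask grid does not match data grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return replace(self, data=data)


def load_bold(path: str | Path, tr: float | None = None) -> BoldSeries:
    """Read a 4D NIfTI; TR taken from the header zooms unless given."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldSeries(data=data, tr=float(tr), affine=img.affine)


def save_bold(series: BoldSeries, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = series.tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a single 3D volume (float32, or int16 for integer label maps)."""
    path = Path(path)
    arr = np.asarray(data)
    dtype = np.int16 if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool else np.float32
    nib.save(nib.Nifti1Image(arr.astype(dtype), np.asarray(affine)), str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine
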