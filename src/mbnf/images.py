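"""In-memory imaging containers and NIfTI round-tripping.

The pipeline's unit of imaging data is :class:`VolumeSeries`, a 4-D scalar
field with a repetition time and a voxel-to-world affine, thin enough to be
built in tests and convertible to/from ``nibabel.Nifti1Image`` at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ShapeMismatchError


@dataclass
class VolumeSeries:
    """A 4-D BOLD series: ``data[x, y, z, t]`` plus TR and affine."""

    data: np.ndarray
    tr: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ShapeMismatchError(f"expected 4-D data, got {self.data.ndim}-D")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ShapeMismatchError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def duration_sec(self) -> float:
        return self.n_vols * self.tr

    def voxel_timecourses(self, mask: np.ndarray) -> np.ndarray:
        """Return a T x Nvox matrix of the series inside a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid_shape:
            raise ShapeMismatchError("mask shape does not match series grid")
        return self.data[mask].T

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data, self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr))
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, tr: float | None = None) -> "VolumeSeries":
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), tr=tr, affine=img.affine)

    @classmethod
    def load(cls, path: str | Path, tr: float | None = None) -> "VolumeSeries":
        return cls.from_nifti(nib.load(str(path)), tr=tr)


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def voxel_world_coordinates(grid_shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """World-space (mm) coordinates of every voxel center; shape grid + (3,)."""
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in grid_shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    world = vox @ np.asarray(affine).T
    return world[..., :3]
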