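"""Minimal 3D brain-image container with a voxel-to-world affine.

All images in this package are dense float32 lattices on an RAS+ grid.
Physical units are millimetres throughout; voxel (i, j, k) maps to world
coordinates via ``affine @ [i, j, k, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["BrainImage"]


@dataclass
class BrainImage:
    """A dense 3D scalar lattice plus its voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities or probabilities, stored as float32.
    affine : ndarray, shape (4, 4)
        Voxel-index to world (mm) mapping, RAS+ convention.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D lattice, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis physical voxel size in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (nx, ny, nz, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        ).astype(np.float64)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def like(self, data: np.ndarray) -> "BrainImage":
        """New image with the same grid but different data."""
        return BrainImage(np.asarray(data, dtype=np.float32), self.affine.copy())

    def integral(self) -> float:
        """Integral of the lattice over physical space (data-units * mm^3)."""
        return float(self.data.sum(dtype=np.float64) * self.voxel_volume)

    def same_grid(self, other: "BrainImage", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data, self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "BrainImage":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=np.float32), img.affine)


def default_affine(shape: tuple[int, int, int], voxel_size_mm) -> np.ndarray:
    """RAS+ affine centring the grid on the world origin."""
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vs)
    aff[:3, 3] = -vs * (np.asarray(shape) - 1) / 2.0
    return aff
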