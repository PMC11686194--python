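"""3D scalar volumes with world-coordinate geometry.

A :class:`Volume` couples a 3D intensity array with its voxel spacing and
world origin, using the voxel-center convention: the world position of
voxel index ``i`` is ``origin + i * spacing``.  All world coordinates are
in millimetres.  Volumes are read and written as NIfTI through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class Volume:
    """A 3D scalar image with spacing and origin in mm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities.
    spacing : array-like of 3 floats
        Voxel spacing per axis, mm.  Must be positive.
    origin : array-like of 3 floats
        World position of voxel (0, 0, 0), mm.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.broadcast_to(np.asarray(self.origin, dtype=float), (3,)).copy()
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    # -- geometry ---------------------------------------------------------

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world points (mm) to continuous voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world points (mm)."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    @property
    def world_min(self) -> np.ndarray:
        return self.origin.copy()

    @property
    def world_max(self) -> np.ndarray:
        return self.origin + (np.asarray(self.shape) - 1) * self.spacing

    def contains(self, points: np.ndarray, margin_mm: float = 0.0) -> np.ndarray:
        """Boolean mask: points inside the field of view, shrunk by margin_mm."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = self.world_min + margin_mm
        hi = self.world_max - margin_mm
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    # -- sampling ---------------------------------------------------------

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolate intensities at world points (mm).

        Points outside the field of view take the nearest in-volume value;
        callers that must not sample outside check :meth:`contains` first.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vox = self.world_to_voxel(pts)
        return map_coordinates(self.data, vox.T, order=1, mode="nearest")

    # -- I/O --------------------------------------------------------------

    def to_nifti(self, path) -> None:
        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms(tuple(self.spacing))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "Volume":
        img = nib.load(str(path))
        affine = img.affine
        data = np.asarray(img.dataobj, dtype=float)
        spacing = np.abs(np.diag(affine)[:3])
        origin = affine[:3, 3].copy()
        return cls(data=data, spacing=spacing, origin=origin)
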