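"""3D scalar volumes with physical spacing, and NIfTI-1 I/O.

Conventions used throughout the package: world coordinates in mm, voxel
indices 0-based, axis order (x, y, z) with axial slices taken along z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class Volume:
    """A 3D intensity (or binary-mask) array on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar field, HU for raw CTA-like volumes, [0, 1] after windowing,
        {0, 1} for masks.
    spacing_mm : tuple of float
        Voxel edge lengths in mm, strictly positive.
    origin_mm : tuple of float
        World coordinate of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent_mm(self) -> tuple[float, float, float]:
        """Edge lengths of the volume's bounding box in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis (1D arrays)."""
        return tuple(
            o + s * np.arange(n)
            for n, s, o in zip(self.shape, self.spacing_mm, self.origin_mm)
        )

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-coordinate points (N, 3) to continuous voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.array(self.origin_mm)) / np.array(self.spacing_mm)

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


def save_nifti(vol: Volume, path: str) -> None:
    """Write a volume as NIfTI-1 with spacing and origin in the affine."""
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    affine[:3, 3] = vol.origin_mm
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), path)


def load_nifti(path: str) -> Volume:
    img = nib.load(path)
    affine = img.affine
    spacing = tuple(np.abs(np.diag(affine)[:3]))
    origin = tuple(affine[:3, 3])
    return Volume(np.asanyarray(img.dataobj), spacing, origin)
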