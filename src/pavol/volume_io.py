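"""3D image volumes with world (mm) geometry.

All downstream geometry — model fitting, tracking, volumetry — is done in
physical millimetres.  :class:`ImageVolume` couples a scalar voxel array with
the affine that maps 0-based voxel indices to world mm, and provides trilinear
sub-voxel sampling for the model fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["ImageVolume", "load_volume", "save_volume"]

#: value returned for samples that fall outside the volume
OUTSIDE_SENTINEL = np.nan


@dataclass
class ImageVolume:
    """A 3D scalar field on an anisotropic voxel grid.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units).
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World position (mm) of voxel index ``(0, 0, 0)``.
    direction
        3x3 orthonormal matrix of axis direction cosines (columns are the
        world directions of the voxel axes).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]
    direction: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"not a scalar 3D volume: data has ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=np.float64).reshape(3)
        )
        self.direction = (
            np.eye(3) if self.direction is None else np.asarray(self.direction, dtype=np.float64).reshape(3, 3)
        )
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal")
        # voxel -> world linear part and its inverse, cached
        self._A = self.direction * self.spacing[np.newaxis, :]
        self._Ainv = np.linalg.inv(self._A)

    # ------------------------------------------------------------------ geometry

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine."""
        aff = np.eye(4)
        aff[:3, :3] = self._A
        aff[:3, 3] = self.origin
        return aff

    def world_from_voxel(self, index) -> np.ndarray:
        """Map (continuous) 0-based voxel indices to world mm.

        Accepts a single triple or an (N, 3) array.
        """
        idx = np.asarray(index, dtype=np.float64)
        return idx @ self._A.T + self.origin

    def voxel_from_world(self, point) -> np.ndarray:
        """Inverse of :meth:`world_from_voxel` (continuous indices)."""
        p = np.asarray(point, dtype=np.float64)
        return (p - self.origin) @ self._Ainv.T

    def contains_world(self, point, margin_mm: float = 0.0) -> np.ndarray:
        """True where world points fall inside the voxel grid.

        ``margin_mm`` shrinks the accepted region inward on every face.
        """
        idx = np.atleast_2d(self.voxel_from_world(point))
        m = margin_mm / self.spacing
        shape = np.array(self.shape)
        ok = np.all((idx >= m) & (idx <= shape - 1 - m), axis=1)
        return ok if np.asarray(point).ndim > 1 else ok[0]

    # ------------------------------------------------------------------ sampling

    def sample_world(self, points) -> np.ndarray:
        """Trilinear intensity at world points; NaN sentinel outside the grid.

        Extrapolation would bias the cylinder fit, so outside samples are
        marked invalid instead.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        idx = self.voxel_from_world(pts)
        vals = map_coordinates(self.data, idx.T, order=1, mode="nearest")
        shape = np.array(self.shape)
        inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
        vals = np.where(inside, vals, OUTSIDE_SENTINEL)
        return vals if np.asarray(points).ndim > 1 else vals[0]


def load_volume(path) -> ImageVolume:
    """Read a single-channel 3D NIfTI into an :class:`ImageVolume`.

    Raises ``ValueError`` for 4D/non-scalar data or non-finite voxels and
    ``FileNotFoundError`` for a missing file.  Intensities are unchanged;
    spacing, origin and direction cosines are taken from the header affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"not a scalar 3D volume: {path} has shape {data.shape}")
    aff = img.affine
    A = aff[:3, :3]
    spacing = np.linalg.norm(A, axis=0)
    direction = A / spacing[np.newaxis, :]
    return ImageVolume(
        data=np.asarray(data, dtype=np.float64),
        spacing=spacing,
        origin=aff[:3, 3].copy(),
        direction=direction,
    )


def save_volume(vol: ImageVolume, path) -> None:
    """Write an :class:`ImageVolume` as NIfTI-1, preserving float data exactly."""
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))
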