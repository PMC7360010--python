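"""3-D activity-concentration images.

An :class:`ActivityImage` is a plain voxel grid of activity concentration in
kBq/mL together with its geometry: isotropic-or-not voxel size in mm and the
world coordinate (mm) of the *center* of voxel (0, 0, 0).  World position of
voxel index ``(i, j, k)`` is ``origin + index * voxel_size``.  Images are
written and read as single-volume NIfTI-1 files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import SchemaError, ValidationError

__all__ = ["ActivityImage", "read_activity_image", "write_activity_image"]


@dataclass
class ActivityImage:
    """Voxel grid of activity concentration.

    Parameters
    ----------
    voxels
        3-D float array, kBq/mL per voxel.
    voxel_size
        Edge lengths of a voxel in mm, one value per axis.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValidationError("activity image must be a non-empty 3-D array")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("activity image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mm^3 == 1e-3 mL)."""
        vx, vy, vz = self.voxel_size
        return vx * vy * vz * 1e-3

    def total_activity_kbq(self) -> float:
        """Total activity of the image: sum(concentration) x voxel volume."""
        return float(self.voxels.sum() * self.voxel_volume_ml)

    def world_to_index(self, xyz) -> np.ndarray:
        """Continuous voxel index of a world point (mm)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def index_grid_world(self):
        """World coordinates of all voxel centers, one 1-D array per axis."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_size[a]
            for a in range(3)
        )

    def copy(self) -> "ActivityImage":
        return ActivityImage(self.voxels.copy(), self.voxel_size, self.origin, dict(self.meta))


def write_activity_image(image: ActivityImage, path) -> None:
    """Write a single-volume NIfTI-1 file with voxel values in kBq/mL."""
    affine = np.diag(list(image.voxel_size) + [1.0])
    affine[:3, 3] = image.origin
    nii = nib.Nifti1Image(image.voxels.astype(np.float32), affine)
    nii.header.set_xyzt_units(xyz="mm")
    nib.save(nii, str(path))


def read_activity_image(path) -> ActivityImage:
    """Read a single 3-D NIfTI-1 volume as an :class:`ActivityImage`.

    Voxel values are interpreted as kBq/mL; voxel size and origin come from
    the affine (which must be diagonal-positive, i.e. axis-aligned).
    4-D or higher-dimensional files are rejected.
    """
    try:
        nii = nib.load(str(path))
    except Exception as exc:  # malformed header
        raise SchemaError(f"not a readable NIfTI file: {path}: {exc}") from exc
    data = np.asanyarray(nii.dataobj)
    if data.ndim != 3:
        raise SchemaError(f"expected a 3-D volume, got {data.ndim}-D: {path}")
    affine = nii.affine
    scales = np.diag(affine)[:3]
    if np.any(scales <= 0) or np.any(affine[:3, :3] - np.diag(scales)):
        raise SchemaError("only axis-aligned, positively oriented affines are supported")
    return ActivityImage(
        data.astype(float),
        voxel_size=tuple(scales),
        origin=tuple(affine[:3, 3]),
    )
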