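"""Core image-grid types shared by every stage of the pipeline.

Conventions
-----------
* Arrays are indexed ``[x, y, z]`` with the z axis last.
* Voxel indices are 0-based; the z index increases cranially.
* Physical z of slice ``k`` is ``origin[2] + k * spacing[2]`` (mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Raised when two grids that must coincide do not."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid of HU values with physical voxel spacing.

    Parameters
    ----------
    values
        HU voxel values, shape ``(nx, ny, nz)``.
    spacing
        Physical voxel size ``(dx, dy, dz)`` in mm, all positive.
    origin
        Physical coordinate of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def pixel_area(self) -> float:
        """In-slice physical area of one voxel in mm^2."""
        return self.spacing[0] * self.spacing[1]

    def slice_z(self, k: int) -> float:
        """Physical z coordinate (mm) of slice index ``k``."""
        return self.origin[2] + k * self.spacing[2]

    def z_grid(self) -> np.ndarray:
        """Physical z coordinates of all acquired slices, caudal to cranial."""
        nz = self.shape[2]
        return self.origin[2] + np.arange(nz) * self.spacing[2]


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid aligned with a parent :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("mask must be 3D")
        object.__setattr__(self, "values", v.astype(bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())

    def like(self, values: np.ndarray) -> "BinaryMask":
        """A new mask on this mask's grid."""
        return BinaryMask(values, self.spacing, self.origin)

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        check_same_grid(self, other)
        return self.like(self.values & other.values)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        check_same_grid(self, other)
        return self.like(self.values | other.values)

    def minus(self, other: "BinaryMask") -> "BinaryMask":
        check_same_grid(self, other)
        return self.like(self.values & ~other.values)


def check_same_grid(a, b) -> None:
    """Raise :class:`GridMismatchError` unless a and b share shape and spacing."""
    if a.values.shape != b.values.shape:
        raise GridMismatchError(
            f"grid shape mismatch: {a.values.shape} vs {b.values.shape}"
        )
    if not np.allclose(a.spacing, b.spacing) or not np.allclose(a.origin, b.origin):
        raise GridMismatchError("grid spacing/origin mismatch")


def mask_like(volume: ImageVolume, values: np.ndarray) -> BinaryMask:
    return BinaryMask(values, volume.spacing, volume.origin)
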