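"""Thoracic SAT/VAT segmentation operators.

The chain is: trim the volume to the standardized thoracic extent around
the lungs, segment the body with per-slice air-cavity filling, threshold
fat inside the body with a closed HU interval, split fat into VAT (inside
the rib-cage interface, after a per-slice morphological opening) and SAT
(the remainder), and remove marrow pseudo-fat inside bone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .grid import BinaryMask, ImageVolume, check_same_grid, mask_like

log = logging.getLogger(__name__)

BODY_THRESHOLD_HU = -300.0


@dataclass(frozen=True)
class FatWindow:
    """Closed HU interval defining adipose tissue; both ends inclusive."""

    lower: float = -170.0
    upper: float = -40.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"fat window lower ({self.lower}) must be < upper ({self.upper})")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.lower) & (values <= self.upper)


@dataclass(frozen=True)
class FatCompartments:
    sat: BinaryMask
    vat: BinaryMask

    def __post_init__(self) -> None:
        check_same_grid(self.sat, self.vat)
        if np.any(self.sat.values & self.vat.values):
            raise ValueError("SAT and VAT masks must be disjoint")


def trim_thoracic_region(
    volume: ImageVolume,
    lung_mask: BinaryMask,
    *masks: BinaryMask,
    superior_margin_mm: float = 15.0,
    inferior_margin_mm: float = 5.0,
) -> tuple[ImageVolume, list[BinaryMask]]:
    """Trim to the thoracic extent: from ``inferior_margin_mm`` below the
    lung base to ``superior_margin_mm`` above the lung apex.

    Margins are converted to whole slices by rounding outward
    (``ceil(mm / dz)``) and clipped to the acquired extent.  Companion
    masks are cropped identically.
    """
    check_same_grid(volume, lung_mask)
    if lung_mask.count() == 0:
        raise ValueError("lung mask is empty; cannot locate thoracic extent")
    zs = np.flatnonzero(lung_mask.values.any(axis=(0, 1)))
    k_base, k_apex = int(zs[0]), int(zs[-1])
    dz = volume.spacing[2]
    k_lo = max(0, k_base - math.ceil(inferior_margin_mm / dz))
    k_hi = min(volume.shape[2] - 1, k_apex + math.ceil(superior_margin_mm / dz))
    new_origin = (volume.origin[0], volume.origin[1], volume.slice_z(k_lo))
    trimmed = ImageVolume(
        volume.values[:, :, k_lo : k_hi + 1], volume.spacing, new_origin
    )
    cropped = [
        BinaryMask(m.values[:, :, k_lo : k_hi + 1], m.spacing, new_origin)
        for m in (lung_mask, *masks)
    ]
    return trimmed, cropped


def _fill_cavities_2d(body2d: np.ndarray) -> np.ndarray:
    """Fill below-threshold (air) components not touching the slice border,
    4-connected."""
    air = ~body2d
    lbl, n = ndimage.label(air, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        return body2d
    border = np.zeros_like(air)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    outside = np.unique(lbl[border & air])
    interior = np.isin(lbl, outside, invert=True) & air
    return body2d | interior


def segment_body(
    volume: ImageVolume, threshold_hu: float = BODY_THRESHOLD_HU
) -> BinaryMask:
    """Threshold the body and fill interior air cavities per axial slice.

    Voxels at or above ``threshold_hu`` seed the body; 2D 4-connected air
    components not touching the lateral image border are filled.
    """
    above = volume.values >= threshold_hu
    out = np.empty_like(above)
    for k in range(volume.shape[2]):
        out[:, :, k] = _fill_cavities_2d(above[:, :, k])
    if not out.any():
        log.warning("segment_body produced an empty mask")
    return mask_like(volume, out)


def segment_fat(
    volume: ImageVolume, body: BinaryMask, window: FatWindow = FatWindow()
) -> BinaryMask:
    """All adipose-tissue voxels within the body: closed-interval HU
    threshold intersected with the body mask."""
    check_same_grid(volume, body)
    return mask_like(volume, window.contains(volume.values) & body.values)


def _opening_2d(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask
    selem = disk(radius)
    out = np.empty_like(mask)
    for k in range(mask.shape[2]):
        out[:, :, k] = ndimage.binary_opening(mask[:, :, k], structure=selem)
    return out


def segment_vat(
    volume: ImageVolume,
    interface_mask: BinaryMask,
    window: FatWindow = FatWindow(),
    opening_radius: int = 1,
) -> BinaryMask:
    """VAT: fat-window voxels inside the SAT/VAT interface (thoracic-cavity
    interior, pre-clipped at the diaphragm), then a per-slice disc opening
    to remove isolated pixels.  ``opening_radius=0`` skips the opening."""
    check_same_grid(volume, interface_mask)
    raw = window.contains(volume.values) & interface_mask.values
    return mask_like(volume, _opening_2d(raw, opening_radius))


def segment_sat(fat: BinaryMask, vat: BinaryMask) -> BinaryMask:
    """SAT: the fat mass with the VAT component removed."""
    return fat.minus(vat)


def remove_marrow_pseudofat(
    sat_or_fat: BinaryMask, bone_mask: BinaryMask, closing_radius: int = 2
) -> BinaryMask:
    """Remove pseudo-fat voxels inside medullary bone: subtract the
    per-slice morphological closing of the bone mask."""
    check_same_grid(sat_or_fat, bone_mask)
    if bone_mask.count() == 0:
        return sat_or_fat
    selem = disk(closing_radius)
    closed = np.empty_like(bone_mask.values)
    for k in range(bone_mask.shape[2]):
        closed[:, :, k] = ndimage.binary_closing(
            bone_mask.values[:, :, k], structure=selem
        )
    return sat_or_fat.like(sat_or_fat.values & ~closed)


def segment_compartments(
    volume: ImageVolume,
    interface_mask: BinaryMask,
    bone_mask: BinaryMask | None = None,
    window: FatWindow = FatWindow(),
    opening_radius: int = 1,
    body_threshold_hu: float = BODY_THRESHOLD_HU,
    marrow_correction: bool = True,
) -> FatCompartments:
    """Full step-(1) chain on an already-trimmed thoracic volume.

    Marrow correction (when enabled and a bone mask is given) is applied to
    the whole fat mass before the SAT/VAT split.
    """
    body = segment_body(volume, threshold_hu=body_threshold_hu)
    fat = segment_fat(volume, body, window)
    if marrow_correction and bone_mask is not None:
        fat = remove_marrow_pseudofat(fat, bone_mask)
    vat = segment_vat(volume, interface_mask, window, opening_radius)
    vat = vat & fat  # opening cannot re-admit voxels outside the fat mass
    sat = segment_sat(fat, vat)
    return FatCompartments(sat=sat, vat=vat)
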