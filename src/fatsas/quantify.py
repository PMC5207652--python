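"""Normalized fat quantity and attenuation-quality measurements.

Fat volumes are normalized by ``L**3`` and areas by ``L**2`` where ``L``
is the diagonal of the tight physical bounding box of the thoracic
skeleton, making measures invariant to isotropic body-size rescaling.
Attenuation quality is summarized by five HU histogram parameters: mean,
median, mode, lower and upper quartile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .grid import BinaryMask, ImageVolume, check_same_grid
from .segmentation import FatWindow

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizingLength:
    """Diagonal (mm) of the box enclosing the thoracic skeleton."""

    L: float

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError("normalizing length must be > 0")


@dataclass(frozen=True)
class HistogramSummary:
    H_m: float
    H_md: float
    H_p: float
    H_lq: float
    H_uq: float
    n_voxels: int

    PARAMS = ("m", "md", "p", "lq", "uq")

    def as_dict(self) -> dict[str, float]:
        return {
            "m": self.H_m, "md": self.H_md, "p": self.H_p,
            "lq": self.H_lq, "uq": self.H_uq,
        }


@dataclass(frozen=True)
class MeasurementRecord:
    subject_id: str
    compartment: str          # "SAT" | "VAT"
    region: str               # "chest" | "abdomen" | "thigh"
    scope: str                # "volume" | "slice@<label>"
    raw: float                # mm^3 for volumes, mm^2 for areas
    normalized: float
    histogram: HistogramSummary | None


def skeletal_diagonal(bone_mask: BinaryMask) -> NormalizingLength:
    """Euclidean diagonal of the axis-aligned tight physical bounding box
    of the skeleton mask.  Per-axis extent spans whole voxels
    (``(max_idx - min_idx + 1) * spacing``)."""
    if bone_mask.count() == 0:
        raise ValueError("bone mask is empty; cannot compute normalizing length")
    idx = np.nonzero(bone_mask.values)
    sq = 0.0
    for ax in range(3):
        extent = (int(idx[ax].max()) - int(idx[ax].min()) + 1) * bone_mask.spacing[ax]
        sq += extent * extent
    return NormalizingLength(math.sqrt(sq))


def histogram_summary(
    hu_values: np.ndarray,
    window: FatWindow = FatWindow(),
    mode_bin_width: float = 1.0,
) -> HistogramSummary:
    """Five-parameter attenuation summary of a sample of HU values.

    Median and quartiles use linear interpolation between order statistics.
    The mode is the center of the fullest ``mode_bin_width``-wide bin over
    the fat window; ties resolve to the most negative bin.
    """
    v = np.asarray(hu_values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot summarize an empty attenuation sample")
    lq, md, uq = np.percentile(v, [25.0, 50.0, 75.0])
    # bins centered on whole-HU values across the fat window
    edges = np.arange(
        window.lower - mode_bin_width / 2,
        window.upper + mode_bin_width,
        mode_bin_width,
    )
    counts, _ = np.histogram(v, bins=edges)
    if counts.sum() == 0:  # sample entirely outside the window
        mode = float(md)
    else:
        i = int(np.argmax(counts))  # first max = most negative bin
        mode = float(edges[i] + mode_bin_width / 2)
    return HistogramSummary(
        H_m=float(v.mean()), H_md=float(md), H_p=mode,
        H_lq=float(lq), H_uq=float(uq), n_voxels=int(v.size),
    )


def measure(
    mask: BinaryMask,
    volume: ImageVolume,
    scope: str,
    L: NormalizingLength,
    subject_id: str = "",
    compartment: str = "",
    region: str = "chest",
    window: FatWindow = FatWindow(),
    slice_index: int | None = None,
) -> MeasurementRecord:
    """Measure a compartment mask: raw volume (mm^3) or slice area (mm^2),
    the normalized value, and the HU histogram summary under the mask.

    For slice scopes pass ``slice_index``; only that axial slice is
    measured.  An empty mask yields a zero-valued record with no histogram.
    """
    check_same_grid(mask, volume)
    if scope == "volume":
        m = mask.values
        hu = volume.values[m]
        raw = float(m.sum()) * volume.voxel_volume
        norm = raw / L.L**3
    else:
        if slice_index is None:
            raise ValueError("slice scope requires slice_index")
        m = mask.values[:, :, slice_index]
        hu = volume.values[:, :, slice_index][m]
        raw = float(m.sum()) * volume.pixel_area
        norm = raw / L.L**2
    if hu.size == 0:
        log.warning("empty mask for %s %s %s", subject_id, compartment, scope)
        hist = None
    else:
        hist = histogram_summary(hu, window=window)
    return MeasurementRecord(
        subject_id=subject_id, compartment=compartment, region=region,
        scope=scope, raw=raw, normalized=norm, histogram=hist,
    )


def records_to_rows(records: list[MeasurementRecord]) -> list[dict]:
    """Flatten records into tidy rows (one per record) for CSV emission."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "compartment": r.compartment,
            "region": r.region,
            "scope": r.scope,
            "raw": r.raw,
            "normalized": r.normalized,
        }
        for p in HistogramSummary.PARAMS:
            row[f"H_{p}"] = r.histogram.as_dict()[p] if r.histogram else np.nan
        row["n_voxels"] = r.histogram.n_voxels if r.histogram else 0
        rows.append(row)
    return rows
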