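"""Standardized anatomic space (SAS) landmark calibration and slice mapping.

A subject's cranio-caudal axis is described by the physical z positions of
ordered vertebral mid-level landmarks (default T2..T10).  Calibration
averages affinely normalized landmark positions over reference subjects to
obtain mean standardized locations ``M_1..M_n`` with ``M_1 = 0`` and
``M_n = 1``.  A piecewise-linear map between a subject's landmarks and the
``M`` grid then assigns every acquired slice a standardized coordinate
``s``; inverting the map selects, for any standardized location, the
nearest acquired slice — original slices are never resampled.

By convention ``s`` increases caudally: ``s = 0`` at the first (most
cranial) landmark and ``s = 1`` at the last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_LANDMARK_LABELS: tuple[str, ...] = (
    "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10",
)


class LandmarkError(ValueError):
    pass


class OutOfStackError(ValueError):
    """Standardized location maps outside the acquired slice stack."""


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered vertebral landmark labels with physical z positions (mm).

    z must be strictly monotone.  Labels run cranial to caudal
    (T2 first); because the z index increases cranially, z is typically
    strictly decreasing over the label order.
    """

    labels: tuple[str, ...]
    z: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        labels = tuple(self.labels)
        if len(labels) < 2:
            raise LandmarkError("need at least 2 landmarks")
        if len(set(labels)) != len(labels):
            raise LandmarkError("landmark labels must be unique")
        if z.shape != (len(labels),):
            raise LandmarkError("one z position per label required")
        d = np.diff(z)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise LandmarkError(
                f"landmark z must be strictly monotone (subject {self.subject_id})"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "z", z)

    @property
    def n(self) -> int:
        return len(self.labels)

    def normalized(self) -> np.ndarray:
        """Affine normalization sending the first landmark to 0, last to 1."""
        z0, z1 = self.z[0], self.z[-1]
        return (self.z - z0) / (z1 - z0)


@dataclass(frozen=True)
class StandardSpaceModel:
    """Calibrated mean standardized landmark locations ``M_1..M_n``."""

    labels: tuple[str, ...]
    M: np.ndarray
    n_refs: int

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if not np.all(np.diff(M) > 0):
            raise LandmarkError("model M must be strictly increasing")
        if abs(M[0]) > 1e-12 or abs(M[-1] - 1.0) > 1e-12:
            raise LandmarkError("model M must span [0, 1]")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "M", M)


def calibrate(reference_landmarks: list[LandmarkSet]) -> StandardSpaceModel:
    """Estimate mean standardized landmark locations from reference subjects.

    Each reference's z positions are affinely normalized to [0, 1] (first
    landmark to 0, last to 1) and the per-landmark arithmetic mean is taken.
    """
    if not reference_landmarks:
        raise LandmarkError("at least one reference landmark set required")
    labels = reference_landmarks[0].labels
    for lm in reference_landmarks[1:]:
        if lm.labels != labels:
            raise LandmarkError(
                f"label mismatch across references: {lm.labels} vs {labels}"
            )
    U = np.stack([lm.normalized() for lm in reference_landmarks])
    M = U.mean(axis=0)
    # exact endpoints despite floating accumulation
    M[0], M[-1] = 0.0, 1.0
    return StandardSpaceModel(labels=labels, M=M, n_refs=len(reference_landmarks))


def _piecewise(x: np.ndarray, nodes_x: np.ndarray, nodes_y: np.ndarray) -> np.ndarray:
    """Piecewise-linear map through (nodes_x, nodes_y) with end-slope
    extrapolation.  nodes_x must be strictly increasing."""
    seg = np.clip(np.searchsorted(nodes_x, x, side="right") - 1, 0, len(nodes_x) - 2)
    x0, x1 = nodes_x[seg], nodes_x[seg + 1]
    y0, y1 = nodes_y[seg], nodes_y[seg + 1]
    return y0 + (x - x0) / (x1 - x0) * (y1 - y0)


def _oriented_nodes(subject: LandmarkSet, model: StandardSpaceModel):
    if subject.labels != model.labels:
        raise LandmarkError("subject labels do not match model labels")
    L, M = subject.z, model.M
    if np.any(np.diff(L) == 0):
        raise LandmarkError("degenerate landmark segment")
    if L[0] > L[-1]:  # orient so the z-node array increases
        return L[::-1].copy(), M[::-1].copy()
    return L, M


def to_sas(subject: LandmarkSet, model: StandardSpaceModel, z) -> np.ndarray | float:
    """Map physical z (mm) to the standardized coordinate s.

    Piecewise linear between landmarks; linear extrapolation with the
    adjacent segment's slope beyond the first/last landmark.
    """
    Lz, Ms = _oriented_nodes(subject, model)
    zz = np.asarray(z, dtype=float)
    s = _piecewise(np.atleast_1d(zz), Lz, Ms)
    return float(s[0]) if zz.ndim == 0 else s


def sas_to_z(subject: LandmarkSet, model: StandardSpaceModel, s) -> np.ndarray | float:
    """Invert the piecewise map: standardized coordinate s -> physical z."""
    Lz, Ms = _oriented_nodes(subject, model)
    # (Ms, Lz) sorted by Ms: Ms may be decreasing after orientation
    if Ms[0] > Ms[-1]:
        Ms, Lz = Ms[::-1].copy(), Lz[::-1].copy()
    ss = np.asarray(s, dtype=float)
    z = _piecewise(np.atleast_1d(ss), Ms, Lz)
    return float(z[0]) if ss.ndim == 0 else z


def nearest_slice(z: float, slice_grid: np.ndarray, subject_id: str | None = None,
                  check_range: bool = True) -> int:
    """Nearest acquired slice to physical z; ties go to the more cranial
    (greater z) slice.  slice_grid must be monotone in z."""
    grid = np.asarray(slice_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("slice_grid must be a non-empty 1D array")
    if len(grid) > 1 and not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("slice_grid must be monotone")
    if check_range:
        dz = abs(grid[1] - grid[0]) if len(grid) > 1 else 0.0
        lo, hi = min(grid[0], grid[-1]), max(grid[0], grid[-1])
        if z < lo - dz / 2 - 1e-9 or z > hi + dz / 2 + 1e-9:
            raise OutOfStackError(
                f"location z={z:.2f} mm outside acquired stack "
                f"[{lo:.2f}, {hi:.2f}] mm (subject {subject_id})"
            )
    d = np.abs(grid - z)
    best = np.min(d)
    tied = np.flatnonzero(np.abs(d - best) < 1e-9)
    # more cranial = greater physical z
    return int(tied[np.argmax(grid[tied])])


def from_sas(subject: LandmarkSet, model: StandardSpaceModel, s: float,
             slice_grid: np.ndarray) -> int:
    """Slice index within the acquired stack for standardized location s."""
    z = sas_to_z(subject, model, float(s))
    return nearest_slice(z, slice_grid, subject_id=subject.subject_id)


def linear_baseline(slice_grid: np.ndarray, s_fraction: float) -> int:
    """Proportional (linear) slice selection between the first and last
    slices of the stack: fraction 0 -> first slice, 1 -> last slice."""
    grid = np.asarray(slice_grid, dtype=float)
    if len(grid) < 1 or grid[0] == grid[-1]:
        raise ValueError("slice grid spans zero physical extent")
    z = grid[0] + s_fraction * (grid[-1] - grid[0])
    return nearest_slice(z, grid, check_range=False)


def half_level_grid(model: StandardSpaceModel) -> tuple[list[str], np.ndarray]:
    """The standardized half-level sampling grid: mid-vertebra nodes plus
    between-vertebrae midpoints (2n-1 locations; 17 for T2..T10)."""
    labels: list[str] = []
    s_vals: list[float] = []
    for i, lab in enumerate(model.labels):
        labels.append(lab)
        s_vals.append(model.M[i])
        if i + 1 < len(model.labels):
            labels.append(f"{lab}-{model.labels[i + 1]}")
            s_vals.append(0.5 * (model.M[i] + model.M[i + 1]))
    return labels, np.asarray(s_vals)


def sas_label(s: float, model: StandardSpaceModel) -> str:
    """Nearest half-level label (mid-vertebra or between-vertebrae) for s.

    Locations beyond the landmark span get the end label with an
    anatomic-direction suffix ("-sup" cranial / "-inf" caudal).
    """
    tol = 1e-9
    if s < model.M[0] - tol:
        return f"{model.labels[0]}-sup"
    if s > model.M[-1] + tol:
        return f"{model.labels[-1]}-inf"
    labels, s_vals = half_level_grid(model)
    d = np.abs(s_vals - s)
    # ties resolve to the more cranial (smaller s) entry: first argmin
    return labels[int(np.argmin(d))]
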