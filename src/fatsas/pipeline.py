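"""In-memory orchestration: simulate -> segment -> calibrate -> map ->
quantify, producing the cohort table the analysis stage consumes.

The CLI wraps these functions with on-disk artifacts; tests call them
directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sas
from .analysis import HIST_PARAMS, CohortTable
from .grid import BinaryMask, ImageVolume
from .quantify import (
    MeasurementRecord,
    NormalizingLength,
    measure,
    skeletal_diagonal,
)
from .segmentation import (
    BODY_THRESHOLD_HU,
    FatCompartments,
    FatWindow,
    segment_compartments,
    trim_thoracic_region,
)
from .synthetic import (
    PhantomParams,
    SingleSlicePhantom,
    SyntheticSubject,
    generate_cohort,
    generate_single_slice_phantom,
)

log = logging.getLogger(__name__)


@dataclass
class SubjectResult:
    subject_id: str
    volume: ImageVolume                   # trimmed
    compartments: FatCompartments
    L: NormalizingLength
    truth_sat: BinaryMask | None = None
    truth_vat: BinaryMask | None = None
    records: list[MeasurementRecord] = field(default_factory=list)


def segment_subject(
    subject: SyntheticSubject,
    window: FatWindow = FatWindow(),
    opening_radius: int = 1,
    body_threshold_hu: float = BODY_THRESHOLD_HU,
    marrow_correction: bool = True,
    interface_override: BinaryMask | None = None,
) -> SubjectResult:
    """Trim to the thoracic extent and run the full segmentation chain.

    ``interface_override`` substitutes a different interface delineation
    (used to emulate a second operator in repeatability analysis).
    """
    iface = interface_override if interface_override is not None else subject.interface_mask
    vol, (lung, bone, iface_t, tsat, tvat) = _trim_all(subject, iface)
    comp = segment_compartments(
        vol,
        iface_t,
        bone_mask=bone,
        window=window,
        opening_radius=opening_radius,
        body_threshold_hu=body_threshold_hu,
        marrow_correction=marrow_correction,
    )
    return SubjectResult(
        subject_id=subject.subject_id,
        volume=vol,
        compartments=comp,
        L=skeletal_diagonal(bone),
        truth_sat=tsat,
        truth_vat=tvat,
    )


def _trim_all(subject: SyntheticSubject, iface: BinaryMask):
    companions = [subject.bone_mask, iface]
    have_truth = subject.truth.sat_mask is not None
    if have_truth:
        companions += [subject.truth.sat_mask, subject.truth.vat_mask]
    vol, cropped = trim_thoracic_region(subject.volume, subject.lung_mask, *companions)
    lung, bone, iface_t = cropped[0], cropped[1], cropped[2]
    tsat = cropped[3] if have_truth else None
    tvat = cropped[4] if have_truth else None
    return vol, (lung, bone, iface_t, tsat, tvat)


def measure_subject(
    result: SubjectResult,
    model: sas.StandardSpaceModel,
    landmarks: sas.LandmarkSet,
    window: FatWindow = FatWindow(),
) -> dict:
    """Whole-volume and per-standardized-level slice measurements."""
    labels, s_grid = sas.half_level_grid(model)
    z_grid = result.volume.z_grid()
    out = {"labels": labels, "slice_index": [], "records": {}}
    masks = {"SAT": result.compartments.sat, "VAT": result.compartments.vat}
    for comp, mask in masks.items():
        out["records"][(comp, "volume")] = measure(
            mask, result.volume, "volume", result.L,
            subject_id=result.subject_id, compartment=comp, window=window,
        )
    for lab, s in zip(labels, s_grid):
        k = sas.from_sas(landmarks, model, float(s), z_grid)
        out["slice_index"].append(k)
        for comp, mask in masks.items():
            out["records"][(comp, f"slice@{lab}")] = measure(
                mask, result.volume, f"slice@{lab}", result.L,
                subject_id=result.subject_id, compartment=comp, window=window,
                slice_index=k,
            )
    return out


def _single_slice_records(
    subject: SyntheticSubject,
    params: PhantomParams,
    L: NormalizingLength,
    window: FatWindow,
    opening_radius: int,
    rng: np.random.Generator,
) -> dict[str, MeasurementRecord]:
    """Segment per-subject abdomen and thigh phantom slices and measure
    them with the same 2D operators (single-slice volumes)."""
    from .segmentation import segment_body, segment_fat, segment_sat, segment_vat, remove_marrow_pseudofat

    recs: dict[str, MeasurementRecord] = {}
    # scale the planted single-slice fat with the subject's chest fat
    sat_scale = subject.truth.sat_volume_mm3 / (subject.truth.L_mm**3 * 0.016)
    vat_scale = subject.truth.vat_volume_mm3 / (subject.truth.L_mm**3 * 0.009)
    for region in ("abdomen", "thigh"):
        ph = generate_single_slice_phantom(
            region,
            params,
            rng,
            vat_fraction=float(np.clip(0.10 * vat_scale * (1 + rng.normal(0, 0.3)), 0.01, 0.3)),
            sat_area_mm2=600.0 * sat_scale * (1 + rng.normal(0, 0.3)),
            fat_window=window,
        )
        body = segment_body(ph.volume)
        fat = segment_fat(ph.volume, body, window)
        fat = remove_marrow_pseudofat(fat, ph.bone_mask)
        vat = segment_vat(ph.volume, ph.interface_mask, window, opening_radius) & fat
        satm = segment_sat(fat, vat)
        for comp, mask in (("SAT", satm), ("VAT", vat)):
            recs[f"{comp}:{region}"] = measure(
                mask, ph.volume, "slice@single", L,
                subject_id=subject.subject_id, compartment=comp, region=region,
                window=window, slice_index=0,
            )
    return recs


def build_cohort_table(
    subjects: list[SyntheticSubject],
    params: PhantomParams,
    window: FatWindow = FatWindow(),
    opening_radius: int = 1,
    body_threshold_hu: float = BODY_THRESHOLD_HU,
    n_calibration: int | None = 20,
    with_peripheral_slices: bool = True,
) -> tuple[CohortTable, sas.StandardSpaceModel, list[SubjectResult]]:
    """Run segmentation + SAS mapping + quantification over a voxelized
    cohort and assemble the analysis table.

    ``n_calibration`` reference subjects (the first ones; None = all)
    feed SAS calibration, mirroring a dedicated calibration set.
    """
    lms = [s.landmarks for s in subjects]
    n_cal = len(lms) if n_calibration is None else min(n_calibration, len(lms))
    model = sas.calibrate(lms[:n_cal])
    labels, _ = sas.half_level_grid(model)

    rows, sat_rows, vat_rows = [], [], []
    hist_rows: dict[str, dict[str, list]] = {
        c: {p: [] for p in HIST_PARAMS} for c in ("SAT", "VAT")
    }
    results = []
    rng_master = np.random.SeedSequence(params.seed + 987654321).spawn(len(subjects))
    for i, subj in enumerate(subjects):
        res = segment_subject(
            subj, window=window, opening_radius=opening_radius,
            body_threshold_hu=body_threshold_hu,
        )
        meas = measure_subject(res, model, subj.landmarks, window=window)
        row = {
            "subject_id": subj.subject_id,
            "group": subj.truth.group,
            "BMI": subj.bmi,
        }
        for comp, key in (("SAT", "SV_C"), ("VAT", "VV_C")):
            rec = meas["records"][(comp, "volume")]
            row[key] = rec.normalized
            prefix = "SVH_C" if comp == "SAT" else "VVH_C"
            for p in HIST_PARAMS:
                row[f"{prefix}_{p}"] = (
                    rec.histogram.as_dict()[p] if rec.histogram else np.nan
                )
        sat_row, vat_row = {}, {}
        for lab in labels:
            sat_rec = meas["records"][("SAT", f"slice@{lab}")]
            vat_rec = meas["records"][("VAT", f"slice@{lab}")]
            sat_row[lab] = sat_rec.normalized
            vat_row[lab] = vat_rec.normalized
            for p in HIST_PARAMS:
                hist_rows["SAT"][p].append(
                    (subj.subject_id, lab, sat_rec.histogram.as_dict()[p] if sat_rec.histogram else np.nan)
                )
                hist_rows["VAT"][p].append(
                    (subj.subject_id, lab, vat_rec.histogram.as_dict()[p] if vat_rec.histogram else np.nan)
                )
        if with_peripheral_slices:
            rng = np.random.default_rng(rng_master[i])
            recs = _single_slice_records(
                subj, params, res.L, window, opening_radius, rng
            )
            row["SA_A"] = recs["SAT:abdomen"].normalized
            row["VA_A"] = recs["VAT:abdomen"].normalized
            row["SA_T"] = recs["SAT:thigh"].normalized
            row["VA_T"] = recs["VAT:thigh"].normalized
        res.records = list(meas["records"].values())
        results.append(res)
        rows.append(row)
        sat_rows.append(sat_row)
        vat_rows.append(vat_row)

    index = pd.Index([s.subject_id for s in subjects], name="subject_id")
    data = pd.DataFrame(rows, index=index).drop(columns=["subject_id"])
    sat_areas = pd.DataFrame(sat_rows, index=index)[labels]
    vat_areas = pd.DataFrame(vat_rows, index=index)[labels]

    def hist_frames(comp):
        out = {}
        for p in HIST_PARAMS:
            df = pd.DataFrame(hist_rows[comp][p], columns=["subject_id", "label", "v"])
            out[p] = df.pivot(index="subject_id", columns="label", values="v")[labels]
        return out

    table = CohortTable(
        data=data,
        grid_labels=labels,
        sat_areas=sat_areas,
        vat_areas=vat_areas,
        sat_slice_hist=hist_frames("SAT"),
        vat_slice_hist=hist_frames("VAT"),
    )
    return table, model, results


def truth_cohort_table(subjects: list[SyntheticSubject]) -> CohortTable:
    """Assemble a cohort table straight from generator ground truth
    (normalized by the analytic skeletal diagonal); no voxel data needed."""
    index = pd.Index([s.subject_id for s in subjects], name="subject_id")
    labels = subjects[0].truth.level_labels
    data, sat_rows, vat_rows = [], [], []
    for s in subjects:
        t = s.truth
        data.append({
            "SV_C": t.sat_volume_mm3 / t.L_mm**3,
            "VV_C": t.vat_volume_mm3 / t.L_mm**3,
            "BMI": s.bmi,
            "group": t.group,
        })
        sat_rows.append(dict(zip(labels, t.sat_area_mm2 / t.L_mm**2)))
        vat_rows.append(dict(zip(labels, t.vat_area_mm2 / t.L_mm**2)))
    return CohortTable(
        data=pd.DataFrame(data, index=index),
        grid_labels=list(labels),
        sat_areas=pd.DataFrame(sat_rows, index=index)[labels],
        vat_areas=pd.DataFrame(vat_rows, index=index)[labels],
    )
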