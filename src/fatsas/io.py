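"""File I/O: NIfTI volumes/masks, landmark and model serialization,
and run manifests.

Volumes are written as uncompressed ``.nii`` so byte content is a pure
function of the data (no gzip timestamps), keeping manifest checksums
reproducible.  Masks are 0/1 uint8 NIfTI with the same affine as their
parent volume.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import BinaryMask, ImageVolume
from .sas import LandmarkSet, StandardSpaceModel


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: ImageVolume, path: Path) -> None:
    img = nib.Nifti1Image(
        volume.values.astype(np.float32), _affine(volume.spacing, volume.origin)
    )
    img.to_filename(str(path))


def read_volume(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def write_mask(mask: BinaryMask, path: Path) -> None:
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.to_filename(str(path))


def read_mask(path: Path) -> BinaryMask:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return BinaryMask(np.asarray(img.dataobj) > 0, spacing, origin)


def write_landmarks(landmark_sets: list[LandmarkSet], path: Path) -> None:
    rows = [
        {"subject_id": lm.subject_id, "label": lab, "z_mm": z}
        for lm in landmark_sets
        for lab, z in zip(lm.labels, lm.z)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path: Path) -> list[LandmarkSet]:
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        out.append(
            LandmarkSet(
                labels=tuple(grp["label"]),
                z=grp["z_mm"].to_numpy(float),
                subject_id=str(sid),
            )
        )
    return out


def write_model(model: StandardSpaceModel, path: Path) -> None:
    payload = {
        "labels": list(model.labels),
        "M": [float(m) for m in model.M],
        "n_refs": model.n_refs,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")


def read_model(path: Path) -> StandardSpaceModel:
    d = json.loads(path.read_text())
    return StandardSpaceModel(tuple(d["labels"]), np.asarray(d["M"]), int(d["n_refs"]))


def file_checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(path: Path, config_hash: str, seed: int, files: dict[str, str]) -> None:
    payload = {"config_hash": config_hash, "seed": seed, "checksums": files}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def checksum_tree(root: Path, exclude: tuple[str, ...] = ("manifest.json",)) -> dict[str, str]:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file() and p.name not in exclude:
            out[str(p.relative_to(root))] = file_checksum(p)
    return out
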