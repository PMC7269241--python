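"""NIfTI, CSV and model serialization.

Volumes travel as NIfTI-1 (``.nii`` or ``.nii.gz``), subject metadata as a
CSV with columns ``subject_id,age,group,converted_24mo,institution``,
affine transforms as a 4x4 matrix in a JSON sidecar, and the reference
model as an ``.npz`` plus a small JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .palz import ReferenceModel
from .preprocessing import AffineTransform
from .synthetic import SubjectRecord
from .volume import VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "read_subject_table",
    "write_subject_table",
    "save_model",
    "load_model",
    "save_transform",
    "load_transform",
]


def read_volume(path) -> VolumeGrid:
    """Read a 3-D NIfTI-1 volume (plain or gzipped)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return VolumeGrid(data=data, affine=np.asarray(img.affine))


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a volume as NIfTI-1; float data is stored as float32."""
    data = volume.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    nib.save(img, str(path))


def write_mask(mask: VolumeGrid, path) -> None:
    """Write a binary mask as an unsigned-integer NIfTI."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


_SUBJECT_COLUMNS = ["subject_id", "age", "group", "converted_24mo", "institution"]


def write_subject_table(records: list[SubjectRecord], path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "age": r.age,
            "group": r.group,
            "converted_24mo": bool(r.converted_24mo),
            "institution": r.institution,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_SUBJECT_COLUMNS).to_csv(path, index=False)


def read_subject_table(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = set(_SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            age=float(row.age),
            group=str(row.group),
            converted_24mo=bool(row.converted_24mo),
            institution=str(row.institution),
        )
        for row in df.itertuples()
    ]


def save_model(model: ReferenceModel, directory) -> None:
    """Persist a reference model as arrays plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(
        directory / "model.npz",
        intercept=model.intercept.data,
        slope=model.slope.data,
        residual_sd=model.residual_sd.data,
        mask=model.mask.data.astype(np.uint8),
        affine=model.mask.affine,
    )
    meta = {
        "n": model.n,
        "mean_age": model.mean_age,
        "age_ssq": model.age_ssq,
        "age_range": list(model.age_range),
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(directory) -> ReferenceModel:
    directory = Path(directory)
    arrays = np.load(directory / "model.npz")
    meta = json.loads((directory / "model.json").read_text())
    affine = arrays["affine"]
    return ReferenceModel(
        intercept=VolumeGrid(arrays["intercept"], affine),
        slope=VolumeGrid(arrays["slope"], affine),
        residual_sd=VolumeGrid(arrays["residual_sd"], affine),
        n=int(meta["n"]),
        mean_age=float(meta["mean_age"]),
        age_ssq=float(meta["age_ssq"]),
        mask=VolumeGrid(arrays["mask"].astype(bool), affine),
        age_range=tuple(meta["age_range"]),
    )


def save_transform(transform: AffineTransform, path) -> None:
    Path(path).write_text(json.dumps({"matrix": transform.matrix.tolist()}, indent=2))


def load_transform(path) -> AffineTransform:
    payload = json.loads(Path(path).read_text())
    return AffineTransform(np.asarray(payload["matrix"]))
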