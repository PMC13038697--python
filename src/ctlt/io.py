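"""File interfaces: NIfTI volumes/masks, measurement CSV, paired-scan CSV.

Lattices are stored on disk in NIfTI's (x, y, z) order and transposed to the
package's (z, y, x) convention on read.  Only the voxel spacing is consumed
from the affine — the statistics computed here are orientation-independent.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .air_calibration import PairedScan
from .volume_model import CTVolume, LungMeasurement, VoxelMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_measurements_csv",
    "read_paired_scans_csv",
    "write_paired_scans_csv",
    "load_dicom_series",
]


def _spacing_from_header(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return (float(zooms[2]), float(zooms[1]), float(zooms[0]))  # (z, y, x)


def read_volume(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI, got shape {data.shape}")
    return CTVolume(values=data.transpose(2, 1, 0), spacing=_spacing_from_header(img))


def write_volume(volume: CTVolume, path: str | Path) -> None:
    sz, sy, sx = volume.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(volume.values.transpose(2, 1, 0).astype(np.float32), affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> tuple[VoxelMask, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return VoxelMask(data.transpose(2, 1, 0) > 0), _spacing_from_header(img)


def write_mask(mask: VoxelMask, spacing: Sequence[float], path: str | Path) -> None:
    sz, sy, sx = spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(mask.selected.transpose(2, 1, 0).astype(np.uint8), affine)
    nib.save(img, str(path))


def write_measurements_csv(
    records: Iterable[tuple[str, str, LungMeasurement]], path: str | Path
) -> None:
    """Write (id, phase, measurement) records with the standard columns."""
    rows = [
        {"id": i, "phase": ph, "vCT_total_ml": m.volume_ml, "nCT_total_hu": m.mean_hu}
        for i, ph, m in records
    ]
    pd.DataFrame(rows, columns=["id", "phase", "vCT_total_ml", "nCT_total_hu"]).to_csv(
        path, index=False
    )


_PAIR_COLUMNS = ["subject_id", "date", "phase", "vCT_total_ml", "nCT_total_hu", "trachea_air_hu"]


def read_paired_scans_csv(path: str | Path) -> list[PairedScan]:
    """Read long-format paired scans: one row per phase ('exp' or 'ins'),
    paired on (subject_id, date)."""
    df = pd.read_csv(path)
    missing = set(_PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["date"] = df["date"].fillna("")
    df["subject_id"] = df["subject_id"].fillna("")
    scans = []
    for (sid, date), grp in df.groupby(["subject_id", "date"], sort=True):
        by_phase = {row.phase: row for row in grp.itertuples()}
        if not {"exp", "ins"} <= set(by_phase):
            raise ValueError(f"{path}: subject {sid} date {date} lacks an exp/ins pair")
        e, i = by_phase["exp"], by_phase["ins"]
        scans.append(
            PairedScan(
                exp=LungMeasurement(e.vCT_total_ml, e.nCT_total_hu),
                ins=LungMeasurement(i.vCT_total_ml, i.nCT_total_hu),
                exp_air_hu=float(e.trachea_air_hu),
                ins_air_hu=float(i.trachea_air_hu),
                subject_id=str(sid),
                scan_date=str(date),
            )
        )
    return scans


def write_paired_scans_csv(scans: Iterable[PairedScan], path: str | Path) -> None:
    rows = []
    for s in scans:
        rows.append({"subject_id": s.subject_id, "date": s.scan_date, "phase": "exp",
                     "vCT_total_ml": s.exp.volume_ml, "nCT_total_hu": s.exp.mean_hu,
                     "trachea_air_hu": s.exp_air_hu})
        rows.append({"subject_id": s.subject_id, "date": s.scan_date, "phase": "ins",
                     "vCT_total_ml": s.ins.volume_ml, "nCT_total_hu": s.ins.mean_hu,
                     "trachea_air_hu": s.ins_air_hu})
    pd.DataFrame(rows, columns=_PAIR_COLUMNS).to_csv(path, index=False)


def load_dicom_series(directory: str | Path) -> CTVolume:
    """Minimal DICOM-series shim: sort slices by position, apply rescale
    slope/intercept, return a (z, y, x) HU volume.  Requires pydicom."""
    import pydicom  # optional dependency

    paths = sorted(Path(directory).glob("*.dcm")) or sorted(Path(directory).iterdir())
    slices = []
    for p in paths:
        if not p.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices under {directory}")
    slices.sort(key=lambda d: float(getattr(d, "ImagePositionPatient", [0, 0, 0])[2]))
    arrays = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(ds.pixel_array.astype(float) * slope + intercept)
    first = slices[0]
    py, px = (float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0]))
    if len(slices) > 1:
        z0 = float(first.ImagePositionPatient[2])
        z1 = float(slices[1].ImagePositionPatient[2])
        sz = abs(z1 - z0) or float(getattr(first, "SliceThickness", 1.0))
    else:
        sz = float(getattr(first, "SliceThickness", 1.0))
    return CTVolume(values=np.stack(arrays, axis=0), spacing=(sz, py, px))
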