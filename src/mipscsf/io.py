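"""Readers and writers: TSV/CSV tables, NIfTI volumes, JSON reports.

All writes are atomic (write to a temp file in the target directory,
then rename) so interrupted runs never leave truncated outputs.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .processing import BlockSeries, RawMIPSSeries
from .volume import MRVolume

__all__ = [
    "read_raw_series",
    "write_raw_series",
    "read_block_series",
    "write_block_series",
    "read_cohort_table",
    "write_cohort_table",
    "read_volume",
    "write_volume",
    "write_mask",
    "write_report",
    "read_report",
]


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix="".join(path.suffixes))
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_raw_series(path) -> RawMIPSSeries:
    """Two-column CSV (time_s, phase_deg) with a header row."""
    df = pd.read_csv(path)
    missing = {"time_s", "phase_deg"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df[["time_s", "phase_deg"]].isna().any().any():
        bad = int(df[["time_s", "phase_deg"]].isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: non-finite value at row {bad}")
    return RawMIPSSeries(
        time_s=df["time_s"].to_numpy(float), phase_deg=df["phase_deg"].to_numpy(float)
    )


def write_raw_series(path, raw: RawMIPSSeries) -> None:
    df = pd.DataFrame({"time_s": raw.time_s, "phase_deg": raw.phase_deg})
    _atomic_write(Path(path), lambda tmp: df.to_csv(tmp, index=False))


def read_block_series(path) -> BlockSeries:
    """TSV with columns time_min, blood_ml, value."""
    df = pd.read_csv(path, sep="\t")
    missing = {"time_min", "blood_ml", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return BlockSeries(
        blood_ml=df["blood_ml"].to_numpy(float),
        time_min=df["time_min"].to_numpy(float),
        value=df["value"].to_numpy(float),
    )


def write_block_series(path, series: BlockSeries) -> None:
    df = pd.DataFrame(
        {"time_min": series.time_min, "blood_ml": series.blood_ml, "value": series.value}
    )
    _atomic_write(Path(path), lambda tmp: df.to_csv(tmp, sep="\t", index=False))


def read_cohort_table(path) -> pd.DataFrame:
    """Cohort TSV with columns time_min, blood_ml, rabbit_1..rabbit_N."""
    df = pd.read_csv(path, sep="\t")
    need = {"time_min", "blood_ml"}
    if not need <= set(df.columns) or not any(c.startswith("rabbit_") for c in df.columns):
        raise ValueError(f"{path}: expected time_min, blood_ml and rabbit_* columns")
    if df.isna().any().any():
        raise ValueError(f"{path}: table contains missing values")
    return df


def write_cohort_table(path, table: pd.DataFrame) -> None:
    _atomic_write(Path(path), lambda tmp: table.to_csv(tmp, sep="\t", index=False))


def read_volume(path) -> MRVolume:
    """Load a NIfTI-1 volume; spacing comes from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return MRVolume(intensity=data, spacing=tuple(float(z) for z in img.header.get_zooms()[:3]))


def write_volume(path, vol: MRVolume) -> None:
    img = nib.Nifti1Image(vol.intensity.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    _atomic_write(Path(path), lambda tmp: nib.save(img, tmp))


def write_mask(path, mask: np.ndarray, spacing) -> None:
    """Write a 0/1 uint8 NIfTI mask."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8), aff)
    img.header.set_zooms(tuple(float(s) for s in spacing))
    _atomic_write(Path(path), lambda tmp: nib.save(img, tmp))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(path, report: dict) -> None:
    payload = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    _atomic_write(Path(path), lambda tmp: Path(tmp).write_text(payload + "\n"))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
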