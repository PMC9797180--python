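"""Reading and writing of the imaging and tabular formats the pipeline touches.

Volumes and masks travel as NIfTI-1 (``.nii``/``.nii.gz``); DICOM series
directories are read-only inputs; feature tables and statistics are RFC-4180
CSV.  Internally everything is (z, y, x); NIfTI files store (x, y, z), so
arrays are transposed on the way in and out.
"""
from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import FeatuniqError, ImageVolume, RoiMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_feature_table",
    "read_feature_table",
]


def _from_nifti(img: nib.Nifti1Image) -> ImageVolume:
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise FeatuniqError(f"expected a 3D NIfTI image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FeatuniqError(f"NIfTI header carries non-positive spacing {zooms}")
    # nibabel array order is (x, y, z); flip to (z, y, x).
    data = np.ascontiguousarray(data.transpose(2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return ImageVolume(data, spacing, origin)


def _read_dicom_series(path: Path) -> ImageVolume:
    reader = sitk.ImageSeriesReader()
    series_ids = reader.GetGDCMSeriesIDs(str(path))
    if len(series_ids) == 0:
        raise FeatuniqError(f"no DICOM series found under {path}")
    if len(series_ids) > 1:
        raise FeatuniqError(
            f"directory {path} holds {len(series_ids)} DICOM series; "
            "split it so each directory holds exactly one"
        )
    files = reader.GetGDCMSeriesFileNames(str(path), series_ids[0])
    reader.SetFileNames(files)
    img = reader.Execute()
    # SimpleITK applies RescaleSlope/Intercept, yielding HU; its array
    # convention is already (z, y, x).
    data = sitk.GetArrayFromImage(img).astype(np.float64)
    sx, sy, sz = img.GetSpacing()
    return ImageVolume(data, (float(sz), float(sy), float(sx)))


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI file or a single-series DICOM directory into HU."""
    p = Path(path)
    if p.is_dir():
        return _read_dicom_series(p)
    if not p.exists():
        raise FeatuniqError(f"no such file: {p}")
    return _from_nifti(nib.load(str(p)))


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with spacing in the header."""
    sz, sy, sx = volume.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = np.asarray(volume.origin)[::-1]
    img = nib.Nifti1Image(volume.data.transpose(2, 1, 0), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike, reference: ImageVolume) -> RoiMask:
    """Read a mask congruent with *reference*; any nonzero voxel is foreground."""
    p = Path(path)
    if not p.exists():
        raise FeatuniqError(f"no such file: {p}")
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FeatuniqError(f"expected a 3D mask, got shape {data.shape}")
    data = data.transpose(2, 1, 0)
    if data.shape != reference.shape:
        raise FeatuniqError(
            f"mask shape {data.shape} does not match reference {reference.shape}"
        )
    return RoiMask(data != 0)


def write_mask(mask: RoiMask, spacing: tuple[float, float, float], path: str | os.PathLike) -> None:
    """Write a binary mask as unsigned 8-bit NIfTI."""
    sz, sy, sx = spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8).transpose(2, 1, 0), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


TABLE_COLUMNS = ["patient", "tissue_region", "category", "feature", "variant", "value"]


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike, overwrite: bool = False) -> None:
    """Write a long-format feature table losslessly (full float precision).

    Columns: patient, tissue_region, category, feature, variant, value.
    """
    p = Path(path)
    if p.exists() and not overwrite:
        raise FeatuniqError(f"{p} exists; pass overwrite=True to replace it")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FeatuniqError(f"feature table is missing columns {missing}")
    table.loc[:, TABLE_COLUMNS].to_csv(p, index=False, float_format="%.17g")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={c: str for c in TABLE_COLUMNS[:-1]}, float_precision="round_trip"
    )
    df["value"] = df["value"].astype(float)
    return df
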