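"""NIfTI and table I/O.

Volumes are written as NIfTI-1 (.nii or .nii.gz) with a synthetic diagonal
affine built from the voxel size (phantoms carry no anatomical space); the TR
is stored in the header's 4th zoom. Gzipped output is written with a fixed
mtime so seeded runs are byte-identical. Tables are tab-separated text.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldSeries, ReHoMap


def synthetic_affine(voxel_size_mm) -> np.ndarray:
    voxel = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    if voxel.size == 1:
        voxel = np.repeat(voxel, 3)
    affine = np.diag(np.append(voxel, 1.0))
    return affine


def _save_nifti(img: nib.Nifti1Image, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith(".gz"):
        raw = img.to_bytes()
        with open(path, "wb") as fh:
            # empty filename + fixed mtime keep the byte stream path-independent
            with gzip.GzipFile(filename="", fileobj=fh, mode="wb", mtime=0,
                               compresslevel=1) as gz:
                gz.write(raw)
    else:
        nib.save(img, str(path))


def write_volume(obj, path, voxel_size_mm=None, tr_s=None) -> Path:
    """Write a BoldSeries, ReHoMap, or bare 3D/4D array as NIfTI."""
    if isinstance(obj, BoldSeries):
        data, voxel, tr = obj.data, obj.voxel_size_mm, obj.tr_s
    elif isinstance(obj, ReHoMap):
        data, voxel, tr = obj.values, obj.voxel_size_mm, None
    else:
        data = np.asarray(obj, dtype=float)
        if data.ndim not in (3, 4):
            raise ValueError("expected a 3D or 4D array")
        voxel = voxel_size_mm if voxel_size_mm is not None else 3.0
        tr = tr_s
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), synthetic_affine(voxel))
    zooms = list(img.header.get_zooms())
    if data.ndim == 4 and tr is not None:
        zooms[3] = tr
        img.header.set_zooms(zooms)
        img.header["pixdim"][4] = tr
    _save_nifti(img, Path(path))
    return Path(path)


def read_series(path, mask=None, tr_s=None) -> BoldSeries:
    """Read a 4D NIfTI as a BoldSeries; TR from the header unless given."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()
    tr = float(tr_s) if tr_s is not None else float(zooms[3])
    if tr <= 0:
        raise ValueError(f"{path}: header has no usable TR; pass tr_s")
    voxel = np.asarray(zooms[:3], dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"{path}: mask shape {mask.shape} does not match volume {data.shape[:3]}"
            )
    return BoldSeries(data, tr, voxel, mask)


def read_map(path) -> tuple:
    """Read a 3D NIfTI; returns (data, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, np.asarray(img.header.get_zooms()[:3], dtype=float)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
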