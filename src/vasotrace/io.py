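"""File I/O: multi-page TIFF volumes, NIfTI export, sidecar JSON records."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile


def write_volume_tiff(path, volume: np.ndarray, scale_16bit: bool = True):
    """Write a 3D volume as a multi-page TIFF (16-bit by default)."""
    vol = np.asarray(volume)
    if scale_16bit and vol.dtype != np.uint16:
        lo, hi = float(vol.min()), float(vol.max())
        span = hi - lo if hi > lo else 1.0
        vol = ((vol - lo) / span * 65535).astype(np.uint16)
    tifffile.imwrite(str(path), vol)


def read_volume_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_mask_tiff(path, mask: np.ndarray):
    tifffile.imwrite(str(path), np.asarray(mask).astype(np.uint8))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(bool)


def write_nifti(path, volume: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)):
    """Export a volume as NIfTI with the voxel size in the affine."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def read_nifti(path):
    """Load a NIfTI volume; returns ``(data, voxel_size_mm)``."""
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asanyarray(img.dataobj), zooms


def write_json(path, record: dict):
    Path(path).write_text(json.dumps(record, indent=2, default=_jsonify))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
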