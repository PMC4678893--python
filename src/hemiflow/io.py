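"""Readers and writers for the pipeline's file formats.

Volumes travel as NIfTI-1 (via nibabel), tabular data as UTF-8 TSV with
a mandatory header row, metadata and ground truth as JSON.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import Parcellation


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a 3-D or 4-D array as NIfTI-1."""
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise ValueError("only 3-D or 4-D volumes are supported")
    img = nib.Nifti1Image(data, np.asarray(affine, float))
    path = Path(path)
    nib.save(img, path)
    return path


def read_volume(path):
    """Read a NIfTI-1 volume; returns ``(data, affine)``.

    Raises with the offending property named if the file is not a 3-D
    or 4-D image with a usable affine.
    """
    img = nib.load(str(path))
    if img.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3-D or 4-D data, got {img.ndim}-D")
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise ValueError(f"{path}: missing or non-finite affine")
    return np.asarray(img.get_fdata()), affine


def read_parcellation(path, region_names, hemisphere=None) -> Parcellation:
    """Read an integer-label parcellation volume."""
    data, affine = read_volume(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: parcellation must be 3-D")
    if not np.allclose(data, np.round(data)):
        raise ValueError(
            f"{path}: parcellation contains non-integer values; cannot be "
            "used as labels"
        )
    return Parcellation(
        data.astype(np.int32), list(region_names), affine,
        region_hemisphere=hemisphere,
    )


def check_affines_match(affine_a, affine_b, what="volumes") -> None:
    if not np.allclose(affine_a, affine_b, atol=1e-6):
        raise ValueError(f"affine mismatch between {what}")


def write_roi_tsv(series: np.ndarray, region_names, path) -> Path:
    """ROI time series as TSV: columns = region names, rows = volumes."""
    df = pd.DataFrame(np.asarray(series).T, columns=list(region_names))
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_roi_tsv(path):
    """Read an ROI TSV; returns ``(series (n_regions, T), region_names)``."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty ROI table")
    return df.to_numpy(float).T, list(df.columns)


def write_matrix_tsv(matrix: np.ndarray, region_names, path) -> Path:
    """Square region x region matrix as TSV (rows = source, cols = target)."""
    df = pd.DataFrame(
        np.asarray(matrix), index=list(region_names),
        columns=list(region_names),
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index_label="source")
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
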