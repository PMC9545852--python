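"""NIfTI and CSV input/output for signal stacks, masks, and T1 maps."""

from __future__ import annotations

import csv
from pathlib import Path

import nibabel as nib
import numpy as np

from .t1_fitting import T1Map

__all__ = ["save_volume", "load_volume", "save_t1_map", "load_t1_map"]

_IDENTITY = np.eye(4)


def save_volume(path, data: np.ndarray, dtype=np.float32) -> Path:
    """Write an array (3D, 4D, or 5D) as a NIfTI volume."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), _IDENTITY)
    nib.save(img, str(path))
    return path


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_t1_map(path_prefix, t1_map: T1Map) -> dict:
    """Write a fitted map as NIfTI volumes plus a diagnostics sidecar CSV.

    Produces ``<prefix>_t1.nii.gz``, ``<prefix>_m0.nii.gz``,
    ``<prefix>_valid.nii.gz``, ``<prefix>_fiterr.nii.gz`` and
    ``<prefix>_diagnostics.csv`` (voxel count, percent invalid).
    Invalid voxels are written as 0 in the T1 volume (NaN does not
    survive integer-minded viewers); ``valid`` is the authority.
    """
    prefix = Path(path_prefix)
    paths = {
        "t1": save_volume(f"{prefix}_t1.nii.gz", np.nan_to_num(t1_map.t1)),
        "m0": save_volume(f"{prefix}_m0.nii.gz", np.nan_to_num(t1_map.m0)),
        "valid": save_volume(f"{prefix}_valid.nii.gz", t1_map.valid_mask, dtype=np.uint8),
        "fit_error": save_volume(f"{prefix}_fiterr.nii.gz", np.nan_to_num(t1_map.fit_error)),
    }
    diag = Path(f"{prefix}_diagnostics.csv")
    with open(diag, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["n_voxels", "percent_invalid"])
        writer.writerow([t1_map.t1.size, round(100.0 * t1_map.invalid_fraction, 4)])
    paths["diagnostics"] = diag
    return paths


def load_t1_map(path_prefix) -> T1Map:
    prefix = Path(path_prefix)
    t1 = load_volume(f"{prefix}_t1.nii.gz")
    valid = load_volume(f"{prefix}_valid.nii.gz").astype(bool)
    t1[~valid] = np.nan
    return T1Map(
        t1=t1,
        m0=load_volume(f"{prefix}_m0.nii.gz"),
        valid_mask=valid,
        fit_error=load_volume(f"{prefix}_fiterr.nii.gz"),
    )
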