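"""Liver ROI definition on T1 maps and per-scan summary statistics.

The region of interest is the liver with large blood vessels removed by
thresholding the fitted T1 (blood T1 is well above parenchymal liver
T1), restricted by default to the single slice where the vessel
cross-section is largest — the slice a reader would pick to contain the
portal vein at its widest.  Scan-level summaries are the median T1, the
interquartile range, and the spatial heterogeneity
``100 * IQR / median`` (percent).

Quantiles use linear interpolation between order statistics (the numpy
default); the IQR-based heterogeneity depends on this convention, so it
is fixed here rather than configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .t1_fitting import T1Map

__all__ = ["EmptyRoiError", "RoiSummary", "build_roi", "summarize_roi"]


class EmptyRoiError(ValueError):
    """Raised when ROI construction or summary finds no usable voxels."""


@dataclass(frozen=True)
class RoiSummary:
    """Per-scan ROI summary: median and IQR of T1 (ms), voxel count, and
    spatial heterogeneity (percent, ``100 * iqr / median``)."""

    subject_id: str
    scanner_id: str
    method: str
    scan_index: int
    median_t1: float
    iqr_t1: float
    n_voxels: int
    heterogeneity: float


def build_roi(t1_map: T1Map, liver_mask: np.ndarray, vessel_threshold: float,
              central_slice: bool = True) -> np.ndarray:
    """Liver ROI: valid fitted voxels below the vessel threshold.

    ``roi = liver_mask & valid & (t1 < vessel_threshold)``.  With
    ``central_slice`` (default) the ROI is restricted to the slice whose
    excluded-vessel cross-section (valid liver voxels at or above the
    threshold) is largest; ``False`` keeps all slices.
    """
    if vessel_threshold <= 0:
        raise ValueError("vessel_threshold must be > 0")
    liver_mask = np.asarray(liver_mask, dtype=bool)
    if liver_mask.shape != t1_map.shape:
        raise ValueError("liver_mask shape does not match the T1 map")

    with np.errstate(invalid="ignore"):
        usable = liver_mask & t1_map.valid_mask
        roi = usable & (t1_map.t1 < vessel_threshold)
    if central_slice and roi.ndim == 3 and roi.shape[2] > 1:
        vessel_like = usable & ~roi
        per_slice = vessel_like.sum(axis=(0, 1))
        z = int(np.argmax(per_slice))
        keep = np.zeros_like(roi)
        keep[:, :, z] = roi[:, :, z]
        roi = keep
    if not roi.any():
        raise EmptyRoiError("ROI is empty after validity and vessel thresholding")
    return roi


def summarize_roi(t1_map: T1Map, roi: np.ndarray, subject_id: str = "",
                  scanner_id: str = "", method: str = "", scan_index: int = 1
                  ) -> RoiSummary:
    """Median / IQR / heterogeneity of the fitted T1 inside the ROI."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != t1_map.shape:
        raise ValueError("roi shape does not match the T1 map")
    values = t1_map.t1[roi & t1_map.valid_mask]
    if values.size == 0:
        raise EmptyRoiError("ROI contains no valid voxels")
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    return RoiSummary(
        subject_id=subject_id,
        scanner_id=scanner_id,
        method=method,
        scan_index=int(scan_index),
        median_t1=float(med),
        iqr_t1=float(iqr),
        n_voxels=int(values.size),
        heterogeneity=float(100.0 * iqr / med),
    )
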