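"""Session-to-summary plumbing shared by the command-line tools and the
study-level analyses: fit one simulated (or loaded) scan, define its
liver ROI, and append the scan's summary to the long-format study table.
"""

from __future__ import annotations

import pandas as pd

from .phantom import LIVER_T1_LITERATURE, ScanSession, Study
from .preproc import average_fb_stack
from .roi_stats import build_roi, summarize_roi
from .rr_metrics import STUDY_TABLE_COLUMNS
from .signal_models import IrAcquisition, VfaAcquisition
from .t1_fitting import fit_map

__all__ = ["fit_session", "study_table", "DEFAULT_VESSEL_THRESHOLD_SCALE"]

#: Vessel-exclusion threshold as a multiple of the literature liver T1
#: at the scan's field strength (blood T1 is roughly twice liver T1).
DEFAULT_VESSEL_THRESHOLD_SCALE = 1.5


def fit_session(session: ScanSession, vessel_threshold: float | None = None,
                max_shift: int = 3, central_slice: bool = True):
    """Fit one scan end to end: (preprocess,) fit, ROI, summarize.

    Free-breathing stacks are registered and magnitude-averaged first.
    ``vessel_threshold`` defaults to 1.5 x the literature liver T1 at the
    session's field strength.  Returns ``(T1Map, RoiSummary)``.
    """
    if vessel_threshold is None:
        vessel_threshold = (DEFAULT_VESSEL_THRESHOLD_SCALE
                            * LIVER_T1_LITERATURE[session.field_strength])

    volumes = session.volumes
    if session.method == "MOLLI":
        acq = IrAcquisition(inversion_times=tuple(session.coords))
        method = "molli"
    else:
        acq = VfaAcquisition(tr=session.tr, flip_angles=tuple(session.coords))
        method = "vfa"
        if session.method == "VFA_FB":
            volumes = average_fb_stack(volumes, max_shift=max_shift)

    t1_map = fit_map(volumes, acq, method, mask=session.liver_mask)
    roi = build_roi(t1_map, session.liver_mask, vessel_threshold,
                    central_slice=central_slice)
    summary = summarize_roi(
        t1_map, roi,
        subject_id=session.subject_id, scanner_id=session.scanner_id,
        method=session.method, scan_index=session.scan_index,
    )
    return t1_map, summary


def study_table(study: Study, vessel_threshold_scale: float = DEFAULT_VESSEL_THRESHOLD_SCALE,
                max_shift: int = 3, central_slice: bool = True) -> pd.DataFrame:
    """Run the fit stage over every session of a study.

    Returns the long-format study table (one row per scan) with the
    column set consumed by the metric and inference modules.
    """
    rows = []
    for session in study.sessions():
        threshold = vessel_threshold_scale * LIVER_T1_LITERATURE[session.field_strength]
        _, summary = fit_session(session, vessel_threshold=threshold,
                                 max_shift=max_shift, central_slice=central_slice)
        rows.append(
            {
                "subject_id": summary.subject_id,
                "scanner_id": summary.scanner_id,
                "vendor": session.vendor,
                "field_strength": session.field_strength,
                "method": summary.method,
                "scan_index": summary.scan_index,
                "median_t1": summary.median_t1,
                "iqr_t1": summary.iqr_t1,
                "n_voxels": summary.n_voxels,
                "heterogeneity": summary.heterogeneity,
            }
        )
    df = pd.DataFrame(rows)
    return df[STUDY_TABLE_COLUMNS + ["iqr_t1", "n_voxels"]]
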