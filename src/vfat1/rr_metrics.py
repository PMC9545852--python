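"""Bias, repeatability, reproducibility, and between-subject statistics
for test-retest, multi-scanner T1 measurements.

All metrics are relative errors in percent, built from the sample
(n-1 denominator) standard deviation:

* bias        = 100 * (mean(scan1, scan2) - reference) / reference
* repeatability RE   = 100 * 1.96 * SD(scan1, scan2) / mean(scan1, scan2)
* reproducibility RE = 100 * 1.96 * SD(across scanners) / mean(across scanners)
* between-subject variation = 100 * 1.96 * SD(across subjects) / mean
* spatial heterogeneity = 100 * IQR / median (computed upstream), averaged
  over the two scans

Repeatability measures the half-width of the 95% interval of relative
variation when all scans are on one machine; reproducibility the same
across machines of different vendors.  Metrics are computed per subject
and then averaged over the cohort, reported with a 95% CI of the mean
(1.96 x SD / sqrt(n)).

The default bias references are literature healthy-liver T1 values:
602 ms at 1.5 T and 752 ms at 3.0 T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import LIVER_T1_LITERATURE

__all__ = [
    "bias_estimate",
    "repeatability_re",
    "reproducibility_re",
    "pairwise_reproducibility",
    "between_subject_variation",
    "summarize_population",
    "MetricReport",
    "compute_metric_report",
]

logger = logging.getLogger(__name__)

STUDY_TABLE_COLUMNS = [
    "subject_id", "scanner_id", "vendor", "field_strength", "method",
    "scan_index", "median_t1", "heterogeneity",
]


def _sd(values) -> float:
    return float(np.std(values, ddof=1))


def bias_estimate(t1_scan1: float, t1_scan2: float, reference_t1: float) -> float:
    """Percent error of the scan-averaged T1 relative to a reference."""
    if reference_t1 <= 0:
        raise ValueError("reference_t1 must be > 0")
    avg = 0.5 * (t1_scan1 + t1_scan2)
    return 100.0 * (avg - reference_t1) / reference_t1


def repeatability_re(t1_scan1: float, t1_scan2: float) -> float:
    """Relative error (%) between two scans on the same scanner:
    ``100 * 1.96 * SD(scan1, scan2) / mean``; for two values the sample
    SD equals ``|s1 - s2| / sqrt(2)``."""
    if t1_scan1 <= 0 or t1_scan2 <= 0:
        raise ValueError("scan values must be > 0")
    mean = 0.5 * (t1_scan1 + t1_scan2)
    return 100.0 * 1.96 * _sd([t1_scan1, t1_scan2]) / mean


def reproducibility_re(t1_by_scanner) -> float:
    """Relative error (%) across scanners: ``100 * 1.96 * SD / mean`` of
    one scan-averaged value per scanner."""
    values = np.asarray(t1_by_scanner, dtype=float)
    if values.size < 2:
        raise ValueError("at least two scanner values are required")
    mean = values.mean()
    if mean == 0:
        raise ValueError("mean of scanner values is zero")
    return 100.0 * 1.96 * _sd(values) / mean


def between_subject_variation(t1_by_subject) -> float:
    """Cohort spread (%) of a measurement on one scanner and method:
    ``100 * 1.96 * SD(across subjects) / mean``."""
    values = np.asarray(t1_by_subject, dtype=float)
    if values.size < 2:
        raise ValueError("at least two subjects are required")
    return 100.0 * 1.96 * _sd(values) / values.mean()


def summarize_population(per_subject_values):
    """Cohort mean and 95% CI half-width (``1.96 * SD / sqrt(n)``)."""
    values = np.asarray(per_subject_values, dtype=float)
    if values.size < 2:
        raise ValueError("at least two values are required")
    return float(values.mean()), float(1.96 * _sd(values) / np.sqrt(values.size))


def _validate_table(table: pd.DataFrame):
    missing = [c for c in STUDY_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table is missing columns: {missing}")
    if table.empty:
        raise ValueError("study table is empty")
    dup = table.duplicated(subset=["subject_id", "scanner_id", "method", "scan_index"])
    if dup.any():
        raise ValueError("(subject, scanner, method, scan) rows must be unique")


def _scanner_means(table: pd.DataFrame) -> pd.DataFrame:
    """Scan-averaged median T1 and heterogeneity per
    (subject, scanner, method) cell; keeps vendor and field labels."""
    return (
        table.groupby(["subject_id", "scanner_id", "vendor", "field_strength",
                       "method"], as_index=False)
        .agg(t1=("median_t1", "mean"), heterogeneity=("heterogeneity", "mean"),
             n_scans=("scan_index", "count"))
    )


def pairwise_reproducibility(table: pd.DataFrame, vendor_pair) -> pd.DataFrame:
    """Per-subject reproducibility RE restricted to two vendors' scanners.

    Computed within each (subject, method, field strength) stratum from
    scan-averaged values; subjects missing either vendor in a stratum
    are skipped with a logged warning.  Returns a long DataFrame with
    columns subject_id, method, field_strength, value.
    """
    _validate_table(table)
    pair = set(vendor_pair)
    if len(pair) != 2:
        raise ValueError("vendor_pair must name two distinct vendors")
    cells = _scanner_means(table[table["vendor"].isin(pair)])
    rows = []
    for (subj, method, fs), grp in cells.groupby(
            ["subject_id", "method", "field_strength"]):
        if set(grp["vendor"]) != pair:
            logger.warning("subject %s lacks vendors %s for %s at %.1f T; skipped",
                           subj, sorted(pair), method, fs)
            continue
        rows.append({"subject_id": subj, "method": method, "field_strength": fs,
                     "value": reproducibility_re(grp["t1"].to_numpy())})
    return pd.DataFrame(rows, columns=["subject_id", "method", "field_strength", "value"])


def per_subject_metrics_by(table: pd.DataFrame, by: str,
                           references: dict | None = None) -> pd.DataFrame:
    """Per-subject bias / repeatability / heterogeneity within each level
    of a stratifying column (e.g. ``field_strength`` or ``vendor``).

    Returns a long DataFrame (metric, method, subject_id, ``by``, value)
    suitable for within-subject comparisons across the levels.
    """
    _validate_table(table)
    if by not in table.columns:
        raise ValueError(f"study table has no column {by!r}")
    references = dict(LIVER_T1_LITERATURE if references is None else references)
    rows = []
    for (subj, method, level), grp in table.groupby(["subject_id", "method", by]):
        cells = _scanner_means(grp)
        biases, repeats = [], []
        for _, cell in cells.iterrows():
            ref = references[cell["field_strength"]]
            scans = grp[grp["scanner_id"] == cell["scanner_id"]]
            scans = scans.sort_values("scan_index")["median_t1"].to_numpy()
            biases.append(100.0 * (scans.mean() - ref) / ref)
            if scans.size == 2:
                repeats.append(repeatability_re(scans[0], scans[1]))
        rows.append(("bias", method, subj, level, float(np.mean(biases))))
        if repeats:
            rows.append(("repeatability_re", method, subj, level,
                         float(np.mean(repeats))))
        rows.append(("heterogeneity", method, subj, level,
                     float(cells["heterogeneity"].mean())))
    return pd.DataFrame(rows, columns=["metric", "method", "subject_id", by, "value"])


@dataclass
class MetricReport:
    """Study-level metric surface.

    ``per_subject``: long DataFrame (metric, method, stratum, subject_id,
    value).  ``population``: one row per (metric, method, stratum) with
    the cohort mean, 95% CI half-width, and n.  ``between_subject``: the
    per-scanner-and-method cohort spread.
    """

    per_subject: pd.DataFrame
    population: pd.DataFrame
    between_subject: pd.DataFrame

    def table2_style(self) -> pd.DataFrame:
        """Population summary pivoted: metric rows x method columns, each
        cell ``mean ± half-width``."""
        df = self.population.copy()
        df["cell"] = [f"{m:.1f} ± {h:.1f}" for m, h in zip(df["mean"], df["ci_half_width"])]
        df["row"] = [f"{metric} [{stratum}]" if stratum != "all" else metric
                     for metric, stratum in zip(df["metric"], df["stratum"])]
        return df.pivot(index="row", columns="method", values="cell")


def compute_metric_report(table: pd.DataFrame, references: dict | None = None,
                          ci_z: float = 1.96) -> MetricReport:
    """Compute the full per-subject and population metric surface.

    Per subject and method: bias, repeatability, and heterogeneity are
    computed per scanner then averaged over the subject's scanners
    (stratum "all"); reproducibility RE is computed per field strength
    across the subject's scanners of that field (scan-averaged values,
    >= 2 scanners required).  Population rows carry the cohort mean and
    ``ci_z * SD / sqrt(n)``.  Missing cells (withdrawn subjects) are
    handled by available-case computation and logged.
    """
    _validate_table(table)
    references = dict(LIVER_T1_LITERATURE if references is None else references)

    per_rows = []
    for (subj, method), grp in table.groupby(["subject_id", "method"]):
        cells = _scanner_means(grp)
        biases, repeats, hets = [], [], []
        for _, cell in cells.iterrows():
            ref = references[cell["field_strength"]]
            scans = grp[grp["scanner_id"] == cell["scanner_id"]]
            scans = scans.sort_values("scan_index")["median_t1"].to_numpy()
            if scans.size == 2:
                biases.append(bias_estimate(scans[0], scans[1], ref))
                repeats.append(repeatability_re(scans[0], scans[1]))
            else:
                logger.warning("subject %s scanner %s %s has %d scan(s); "
                               "repeatability skipped", subj, cell["scanner_id"],
                               method, scans.size)
                biases.append(100.0 * (scans.mean() - ref) / ref)
            hets.append(cell["heterogeneity"])
        per_rows.append(("bias", method, "all", subj, float(np.mean(biases))))
        if repeats:
            per_rows.append(("repeatability_re", method, "all", subj,
                             float(np.mean(repeats))))
        per_rows.append(("heterogeneity", method, "all", subj, float(np.mean(hets))))
        for fs, fgrp in cells.groupby("field_strength"):
            if len(fgrp) >= 2:
                per_rows.append(("reproducibility_re", method, f"{fs}T", subj,
                                 reproducibility_re(fgrp["t1"].to_numpy())))
            else:
                logger.warning("subject %s has %d scanner(s) at %.1f T for %s; "
                               "reproducibility skipped", subj, len(fgrp), fs, method)

    per_subject = pd.DataFrame(
        per_rows, columns=["metric", "method", "stratum", "subject_id", "value"])

    pop_rows = []
    for (metric, method, stratum), grp in per_subject.groupby(
            ["metric", "method", "stratum"]):
        vals = grp["value"].to_numpy()
        if vals.size >= 2:
            mean = float(vals.mean())
            half = float(ci_z * _sd(vals) / np.sqrt(vals.size))
        else:
            mean, half = float(vals.mean()), float("nan")
        pop_rows.append({"metric": metric, "method": method, "stratum": stratum,
                         "mean": mean, "ci_half_width": half, "n": vals.size})
    population = pd.DataFrame(pop_rows)

    bsv_rows = []
    cells = _scanner_means(table)
    for (scanner, method), grp in cells.groupby(["scanner_id", "method"]):
        if len(grp) >= 2:
            bsv_rows.append({"scanner_id": scanner, "method": method,
                             "value": between_subject_variation(grp["t1"].to_numpy()),
                             "n_subjects": len(grp)})
    between_subject = pd.DataFrame(bsv_rows)

    return MetricReport(per_subject=per_subject, population=population,
                        between_subject=between_subject)
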