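"""Cohort-level error summaries: threshold sensitivity, manual-vs-auto, normalization.

Three error sources are summarized the same way — mean, sample standard
deviation (n-1 denominator), maximum and count — and assembled into one
three-row report:

1. *threshold choice*: per contact x tract, the spread (max - min) of the
   automated distance across the candidate binarization thresholds;
2. *measurement technique*: |manual axial - automated 3D| per measurable
   contact x tract, with the not-measurable bookkeeping the axial restriction
   induces;
3. *normalization*: the landmark-distance error after outlier exclusion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .distance_measurement import MeasurementRecord
from .normalization_error import LandmarkMeasurement

__all__ = [
    "SummaryStats",
    "SensitivityRecord",
    "summarize",
    "threshold_sensitivity",
    "manual_vs_auto",
    "normalization_summary",
    "build_report",
    "render_text",
    "write_report",
    "read_report",
]

SENSITIVITY_CSV_COLUMNS = [
    "patient_id",
    "hemisphere",
    "tract",
    "contact_index",
    "percent",
    "d_auto_mm",
]

REPORT_SOURCES = ("threshold_binarization", "measurement_technique", "mni_normalization")


@dataclass(frozen=True)
class SummaryStats:
    """Mean / sample SD / max / n of an error series (all distances in mm)."""

    n: int
    mean: float
    sd: float
    max: float


def summarize(values: Sequence[float]) -> SummaryStats:
    """Arithmetic mean, sample SD (n-1; 0 for a singleton), max and count."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty series")
    if np.any(~np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    sd = 0.0 if arr.size == 1 else float(np.std(arr, ddof=1))
    return SummaryStats(n=int(arr.size), mean=float(np.mean(arr)), sd=sd, max=float(np.max(arr)))


@dataclass
class SensitivityRecord:
    """Automated distances of one contact x tract across candidate thresholds."""

    patient_id: str
    hemisphere: str
    tract: str
    contact_index: int
    distances_by_percent: dict  # percent -> d_auto mm (only realized thresholds)
    spread: float  # max - min over available percents; NaN if < 2 available

    @property
    def assessable(self) -> bool:
        return math.isfinite(self.spread)


def threshold_sensitivity(
    sensitivity: pd.DataFrame,
) -> tuple[list[SensitivityRecord], SummaryStats]:
    """Per-contact spread of automated distances over the threshold candidates.

    Input is the long-form sweep table (one row per contact x tract x percent
    with its automated distance; thresholds whose mask was empty are simply
    absent).  For each contact x tract group with at least two realized
    thresholds the spread is ``max - min``; groups with fewer are kept in the
    record list but marked unassessable and excluded from the cohort summary.
    """
    missing = set(SENSITIVITY_CSV_COLUMNS) - set(sensitivity.columns)
    if missing:
        raise ValueError(f"sensitivity table missing columns {sorted(missing)}")
    records: list[SensitivityRecord] = []
    keys = ["patient_id", "hemisphere", "tract", "contact_index"]
    for (pid, hemi, tract, ci), grp in sensitivity.groupby(keys, sort=True):
        d = {
            float(p): float(v)
            for p, v in zip(grp["percent"], grp["d_auto_mm"])
            if np.isfinite(v)
        }
        vals = np.array(list(d.values()))
        spread = float(vals.max() - vals.min()) if len(vals) >= 2 else float("nan")
        records.append(
            SensitivityRecord(
                patient_id=str(pid),
                hemisphere=str(hemi),
                tract=str(tract),
                contact_index=int(ci),
                distances_by_percent=d,
                spread=spread,
            )
        )
    spreads = [r.spread for r in records if r.assessable]
    if not spreads:
        raise ValueError("no contact x tract group has >= 2 realized thresholds")
    return records, summarize(spreads)


def manual_vs_auto(
    records: Sequence[MeasurementRecord],
) -> tuple[np.ndarray, SummaryStats, int, int]:
    """Differences between the two measurement techniques plus bookkeeping.

    Returns ``(differences, stats, n_unmeasurable, n_measured)``: the absolute
    differences |manual - auto| over records where the manual reading was
    possible, their summary, the number of records where the tract was absent
    on the contact's axial slice, and the complementary count of measured
    distances (total records minus unmeasurable ones).
    """
    n_total = len(records)
    n_unmeasurable = sum(1 for r in records if not r.manual_measurable)
    n_measured = n_total - n_unmeasurable
    diffs = np.array(
        [
            abs(r.d_manual - r.d_auto)
            for r in records
            if r.manual_measurable and r.auto_measurable
        ],
        dtype=float,
    )
    stats = summarize(diffs)
    return diffs, stats, n_unmeasurable, n_measured


def normalization_summary(retained: Sequence[LandmarkMeasurement]) -> SummaryStats:
    """Summary of landmark-distance errors over the retained (non-outlier) cases."""
    return summarize([m.error for m in retained])


# ---------------------------------------------------------------------------
# Report


def _row(source: str, stats: SummaryStats, **extra) -> dict:
    row = {
        "source": source,
        "n": stats.n,
        "mean_mm": stats.mean,
        "sd_mm": stats.sd,
        "max_mm": stats.max,
    }
    row.update(extra)
    return row


def build_report(
    sensitivity_stats: Optional[SummaryStats],
    manual_auto_stats: Optional[SummaryStats],
    normalization_stats: Optional[SummaryStats],
    n_manual_unmeasurable: Optional[int] = None,
    n_manual_measured: Optional[int] = None,
    n_norm_excluded: Optional[int] = None,
) -> dict:
    """Assemble the three-row error-summary report (JSON-serializable)."""
    for name, stats in (
        ("threshold_binarization", sensitivity_stats),
        ("measurement_technique", manual_auto_stats),
        ("mni_normalization", normalization_stats),
    ):
        if stats is None:
            raise ValueError(f"missing report section: {name}")
    rows = [
        _row("threshold_binarization", sensitivity_stats),
        _row(
            "measurement_technique",
            manual_auto_stats,
            **(
                {}
                if n_manual_unmeasurable is None
                else {
                    "n_unmeasurable": int(n_manual_unmeasurable),
                    "n_measured": int(n_manual_measured),
                }
            ),
        ),
        _row(
            "mni_normalization",
            normalization_stats,
            **({} if n_norm_excluded is None else {"n_excluded": int(n_norm_excluded)}),
        ),
    ]
    return {"rows": rows}


_ROW_TITLES = {
    "threshold_binarization": "Choice of threshold for binarization",
    "measurement_technique": "Technique of distance measurements",
    "mni_normalization": "Normalization into standard space",
}


def render_text(report: dict) -> str:
    """Human-readable rendering: 'mean ± sd mm / max mm (n=...)' per error source."""
    lines = ["Summary of measured errors", "=" * 26]
    for row in report["rows"]:
        title = _ROW_TITLES.get(row["source"], row["source"])
        lines.append(
            f"{title:<40s} {row['mean_mm']:.2f} ± {row['sd_mm']:.2f} mm"
            f"   max {row['max_mm']:.2f} mm   (n={row['n']})"
        )
    return "\n".join(lines) + "\n"


def write_report(report: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())
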