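"""Groundwater-quality threshold exceedance analysis on the port × day grid.

Classifies every monitoring observation against regulatory threshold values
(defaults follow the Chinese groundwater quality standard GB14848: 700 µg/L
toluene, 0.3 mg/L iron), then derives the summary statistics used to describe
plume behaviour: fraction of monitoring points exceeding, farthest exceeding
port per day (plume extent), and first exceedance day per port.

Conventions: a value equal to the limit counts as exceeding (≥ limit);
censored observations — true value below the detection limit, which sits far
below both thresholds — are classified ``censored`` and never count as
exceeding, but they do count as monitoring points in denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = ["ThresholdSet", "ExceedanceReport", "PlumeMetrics",
           "exceedance_matrix", "plume_metrics", "GB14848"]


@dataclass(frozen=True)
class ThresholdSet:
    """Analyte → regulatory limit, in each analyte's monitoring units."""

    limits: Mapping[str, float]

    def __post_init__(self):
        for analyte, limit in self.limits.items():
            if limit <= 0:
                raise ValueError(f"threshold for {analyte!r} must be > 0, got {limit}")

    def limit_for(self, analyte: str) -> float:
        if analyte not in self.limits:
            raise KeyError(
                f"no threshold defined for analyte {analyte!r}; "
                f"available: {sorted(self.limits)}"
            )
        return self.limits[analyte]


#: GB14848 limits: toluene 700 µg/L, iron 0.3 mg/L
GB14848 = ThresholdSet({"toluene": 700.0, "fe2_dissolved": 0.3})


@dataclass
class ExceedanceReport:
    """Classified observations plus summary accessors.

    ``data`` is the input monitoring table with ``status`` in
    {exceed, comply, censored} and the ``limit`` applied to each row.
    """

    data: pd.DataFrame
    thresholds: ThresholdSet = field(default=GB14848)

    def matrix(self, column_id: str, analyte: str) -> pd.DataFrame:
        """day × distance status grid for one column and analyte."""
        sub = self.data[
            (self.data["column_id"] == column_id) & (self.data["analyte"] == analyte)
        ]
        return sub.pivot(index="day", columns="distance_m", values="status")

    def _select(self, day=None, column_id=None, analyte=None) -> pd.DataFrame:
        sub = self.data
        if day is not None:
            sub = sub[np.isclose(sub["day"].astype(float), day)]
        if column_id is not None:
            sub = sub[sub["column_id"] == column_id]
        if analyte is not None:
            sub = sub[sub["analyte"] == analyte]
        return sub

    def fraction_exceeding(self, day=None, column_id=None, analyte=None) -> float:
        """Percent of selected monitoring points with status 'exceed'."""
        sub = self._select(day, column_id, analyte)
        if sub.empty:
            return float("nan")
        return 100.0 * float((sub["status"] == "exceed").sum()) / len(sub)

    def exceed_count(self, day=None, column_id=None, analyte=None) -> int:
        sub = self._select(day, column_id, analyte)
        return int((sub["status"] == "exceed").sum())

    def max_extent(self, analyte: str, column_id: Optional[str] = None) -> pd.Series:
        """Farthest exceeding port distance (m) per day; NaN when none."""
        sub = self._select(column_id=column_id, analyte=analyte)
        ex = sub[sub["status"] == "exceed"]
        days = sorted(sub["day"].unique())
        extent = ex.groupby("day")["distance_m"].max()
        return extent.reindex(days)

    def first_exceed_day(self, analyte: str, column_id: Optional[str] = None) -> pd.Series:
        """Earliest exceeding day per port distance; ports never exceeding omitted."""
        sub = self._select(column_id=column_id, analyte=analyte)
        ex = sub[sub["status"] == "exceed"]
        if ex.empty:
            return pd.Series(dtype=float, name="first_exceed_day")
        out = ex.groupby("distance_m")["day"].min()
        out.name = "first_exceed_day"
        return out


def exceedance_matrix(
    table: pd.DataFrame, thresholds: ThresholdSet = GB14848
) -> ExceedanceReport:
    """Classify every monitoring observation against its analyte threshold.

    Raises ``KeyError`` if the table holds an analyte without a threshold —
    silent skipping would understate exceedance.
    """
    analytes = sorted(table["analyte"].unique())
    limits = {a: thresholds.limit_for(a) for a in analytes}  # raises on missing
    data = table.copy()
    lim = data["analyte"].map(limits).astype(float)
    censored = data["censored"].astype(bool) if "censored" in data else pd.Series(False, index=data.index)
    status = np.where(
        censored, "censored",
        np.where(data["value"].astype(float) >= lim, "exceed", "comply"),
    )
    data["status"] = status
    data["limit"] = lim
    return ExceedanceReport(data=data, thresholds=thresholds)


@dataclass(frozen=True)
class PlumeMetrics:
    """Plume descriptors for one analyte (both empty-safe)."""

    max_extent: pd.Series  # day → farthest exceeding distance, m (NaN if none)
    first_exceed_day: pd.Series  # distance → first exceeding day


def plume_metrics(
    report: ExceedanceReport, analyte: str, column_id: Optional[str] = None
) -> PlumeMetrics:
    """Extract plume extent and first-exceedance metrics from a report."""
    return PlumeMetrics(
        max_extent=report.max_extent(analyte, column_id),
        first_exceed_day=report.first_exceed_day(analyte, column_id),
    )
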