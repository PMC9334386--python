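"""Daily discharge series container, water-year arithmetic, and record screening.

A :class:`DailyFlowSeries` wraps a date-indexed pandas Series of daily mean
discharge for one gauge.  Missing days are NaN.  Feb 29 is dropped on
construction so every year has exactly 365 days, which keeps rolling-window
and water-year arithmetic uniform between generated and observed records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DailyFlowSeries",
    "ScreeningError",
    "ScreeningReport",
    "water_year",
    "screen_record",
]

DAYS_PER_YEAR = 365


class ScreeningError(ValueError):
    """Raised when a gauge record fails the completeness screen."""


def water_year(index: pd.DatetimeIndex, start_month: int = 10) -> np.ndarray:
    """Water-year label for each date (year in which the water year *ends*).

    With the default USGS convention (Oct 1 - Sep 30), 1999-10-01 through
    2000-09-30 are all labelled 2000.
    """
    years = index.year.to_numpy()
    if start_month == 1:
        return years
    return years + (index.month.to_numpy() >= start_month)


@dataclass
class DailyFlowSeries:
    """Daily mean discharge for one gauge.

    Parameters
    ----------
    gauge_id : str
        Identifier of the gauge (or reach) the record belongs to.
    flows : pandas.Series
        Daily mean discharge with a DatetimeIndex; NaN marks missing days.
        Feb 29 entries are dropped.
    units : str
        ``"cfs"`` or ``"cms"``.
    drainage_area_km2 : float, optional
        Contributing drainage area; required by area-normalised indices.
    """

    gauge_id: str
    flows: pd.Series
    units: str = "cfs"
    drainage_area_km2: float | None = None
    n_feb29_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.flows.index, pd.DatetimeIndex):
            self.flows = self.flows.copy()
            self.flows.index = pd.DatetimeIndex(self.flows.index)
        idx = self.flows.index
        feb29 = (idx.month == 2) & (idx.day == 29)
        if feb29.any():
            self.n_feb29_dropped = int(feb29.sum())
            self.flows = self.flows[~feb29]
            idx = self.flows.index
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError("dates must be strictly increasing and unique")
        vals = self.flows.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("discharge must be non-negative or missing")
        self.flows = self.flows.astype(float)

    def __len__(self) -> int:
        return len(self.flows)

    @property
    def values(self) -> np.ndarray:
        return self.flows.to_numpy()

    def water_years(self, start_month: int = 10) -> np.ndarray:
        return water_year(self.flows.index, start_month=start_month)

    def with_flows(self, flows: pd.Series) -> "DailyFlowSeries":
        return replace(self, flows=flows)

    def to_cms(self) -> "DailyFlowSeries":
        if self.units == "cms":
            return self
        return replace(self, flows=self.flows * 0.0283168466, units="cms")


@dataclass
class ScreeningReport:
    gauge_id: str
    complete_years: list[int]
    dropped_years: dict[int, int]  # water year -> missing-day count
    max_missing_days: int
    min_years: int

    @property
    def n_complete(self) -> int:
        return len(self.complete_years)

    @property
    def passed(self) -> bool:
        return self.n_complete >= self.min_years


def screen_record(
    series: DailyFlowSeries,
    max_missing_days: int = 30,
    min_years: int = 15,
    start_month: int = 10,
) -> tuple[DailyFlowSeries, ScreeningReport]:
    """Retain water years with at most `max_missing_days` missing days.

    A water year is complete when at least ``365 - max_missing_days`` daily
    values are present (days absent from the index count as missing, so
    partial leading/trailing years are dropped too).  Fails the gauge when
    fewer than `min_years` complete years remain.

    Returns the series restricted to complete water years plus a report.

    Raises
    ------
    ScreeningError
        If fewer than `min_years` complete water years are found.
    """
    if len(series) == 0:
        raise ScreeningError(f"gauge {series.gauge_id}: empty record")
    wy = series.water_years(start_month=start_month)
    valid = series.flows.notna().to_numpy()
    counts = pd.Series(valid.astype(int)).groupby(wy).sum()
    missing = DAYS_PER_YEAR - counts
    complete = missing.index[missing <= max_missing_days].tolist()
    dropped = {int(y): int(m) for y, m in missing[missing > max_missing_days].items()}
    report = ScreeningReport(
        gauge_id=series.gauge_id,
        complete_years=[int(y) for y in complete],
        dropped_years=dropped,
        max_missing_days=max_missing_days,
        min_years=min_years,
    )
    if not report.passed:
        raise ScreeningError(
            f"gauge {series.gauge_id}: only {report.n_complete} complete water "
            f"years (< {min_years} required); dropped={dropped}"
        )
    keep = np.isin(wy, complete)
    screened = series.with_flows(series.flows[keep])
    return screened, report
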