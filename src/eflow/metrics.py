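"""Hydrologic indices of magnitude, duration, frequency, timing and rate.

Computes the 41-index suite widely used in alteration assessments (codes
after Olden & Poff): means and monthly means (MA), baseflow ratios (ML),
area-normalised maxima (MH), rolling-window annual extremes (DL/DH), pulse
durations and counts (DL16/DH15, FL1/FH1, FH6/FH7), zero-flow days (DL18),
Colwell's constancy and predictability (TA1/TA2), and day-over-day rise/fall
rates and reversals (RA1/RA3/RA8).

Conventions (documented once, config-exposed where noted):

* Years are water years (Oct-Sep) by default; rolling windows are trailing
  and must lie fully inside one water year.
* Low/high pulse thresholds are the 25th/75th percentiles of all daily flows
  in the screened record; pulses are strict excursions (< low, > high).
* Flood thresholds for FH6/FH7 are 3x and 7x the median daily flow.
* Colwell matrices use calendar-month periods and 11 logarithmically spaced
  flow states between the record's positive min and max; zero flows occupy a
  reserved 12th state.  Entropies are natural-log; the denominator is
  log(n_states + 1).
* RA3 is reported as a positive magnitude (mean |negative change|).
* Counts (DL18, pulse counts, reversals) are prorated to a 365-day year when
  a retained year has missing days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import DailyFlowSeries

__all__ = [
    "MetricVector",
    "MissingDrainageAreaError",
    "MAGNITUDE_CODES",
    "DURATION_CODES",
    "FREQUENCY_CODES",
    "TIMING_CODES",
    "RATE_CODES",
    "ALL_METRIC_CODES",
    "ROLLING_WINDOWS",
    "magnitude_metrics",
    "duration_metrics",
    "frequency_metrics",
    "timing_metrics",
    "rate_metrics",
    "compute_metric_vector",
    "colwell",
]

#: trailing-window lengths (days) for DL1-5 / DH1-5, in index order
ROLLING_WINDOWS = (1, 3, 7, 30, 90)

MONTH_CODES = [f"MA{i}" for i in range(12, 24)]  # MA12=Jan ... MA23=Dec
MAGNITUDE_CODES = ["MA1", "MA2", "MA3", *MONTH_CODES, "MA41", "ML17", "ML19", "MH20"]
DURATION_CODES = [f"DL{i}" for i in range(1, 6)] + ["DL16", "DL18"] + [
    f"DH{i}" for i in range(1, 6)
] + ["DH15"]
FREQUENCY_CODES = ["FL1", "FH1", "FH6", "FH7"]
TIMING_CODES = ["TA1", "TA2"]
RATE_CODES = ["RA1", "RA3", "RA8"]
ALL_METRIC_CODES = (
    MAGNITUDE_CODES + DURATION_CODES + FREQUENCY_CODES + TIMING_CODES + RATE_CODES
)

AREA_CODES = {"MA41", "MH20"}


class MissingDrainageAreaError(ValueError):
    """Area-normalised index requested but the series carries no area."""


@dataclass
class MetricVector:
    """Named hydrologic-index values for one gauge record."""

    gauge_id: str
    values: dict[str, float]
    n_years: int = 0
    notes: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, code: str) -> float:
        return self.values[code]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.gauge_id)


def _frame(series: DailyFlowSeries, start_month: int = 10) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "flow": series.flows.to_numpy(),
            "wy": series.water_years(start_month=start_month),
            "month": series.flows.index.month,
        }
    )
    return df.dropna(subset=["flow"])


def magnitude_metrics(series: DailyFlowSeries, start_month: int = 10) -> dict[str, float]:
    """MA1-3, MA12-23 (monthly means Jan-Dec), MA41, ML17, ML19, MH20."""
    df = _frame(series, start_month)
    flow = df["flow"]
    out: dict[str, float] = {}
    mean = float(flow.mean())
    out["MA1"] = mean
    out["MA2"] = float(flow.median())
    out["MA3"] = float(flow.std(ddof=1) / mean * 100.0) if mean > 0 else 0.0
    monthly = flow.groupby(df["month"]).mean()
    for m in range(1, 13):
        out[f"MA{11 + m}"] = float(monthly.get(m, np.nan))
    grp = flow.groupby(df["wy"])
    ann_mean = grp.mean()
    ann_min = grp.min()
    ann_max = grp.max()
    min7 = grp.apply(lambda s: s.rolling(7, min_periods=7).mean().min())
    out["ML17"] = float((min7 / ann_mean).dropna().mean())
    out["ML19"] = float((ann_min / ann_mean * 100.0).mean())
    area = series.drainage_area_km2
    if area is None:
        raise MissingDrainageAreaError(
            f"gauge {series.gauge_id}: MA41/MH20 require drainage_area_km2"
        )
    out["MA41"] = float(ann_mean.mean() / area)
    out["MH20"] = float(ann_max.mean() / area)
    return out


def _annual_rolling_extreme(grp, window: int, kind: str) -> pd.Series:
    def f(s: pd.Series) -> float:
        r = s.rolling(window, min_periods=window).mean()
        return r.min() if kind == "min" else r.max()

    return grp.apply(f).dropna()


def _runs(mask: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True."""
    lengths = []
    n = 0
    for v in mask:
        if v:
            n += 1
        elif n:
            lengths.append(n)
            n = 0
    if n:
        lengths.append(n)
    return lengths


def _pulse_stats(df: pd.DataFrame, mask: np.ndarray) -> tuple[float, float]:
    """(mean annual pulse count, mean of per-year median pulse durations).

    Counts are prorated to 365 days for years with missing data; years with
    no pulses are omitted from the duration average (0 when no year has any).
    """
    counts, medians = [], []
    for _, sub in pd.Series(mask).groupby(df["wy"].to_numpy()):
        lengths = _runs(sub.to_numpy())
        counts.append(len(lengths) * 365.0 / len(sub))
        if lengths:
            medians.append(float(np.median(lengths)))
    return float(np.mean(counts)), float(np.mean(medians)) if medians else 0.0


def duration_metrics(series: DailyFlowSeries, start_month: int = 10) -> dict[str, float]:
    """DL1-5/DH1-5 rolling annual extremes, DL16/DH15 pulse durations, DL18.

    The longest window (90 d) requires at least 90 retained days in a water
    year; shorter years are skipped for that window only.
    """
    df = _frame(series, start_month)
    grp = df["flow"].groupby(df["wy"])
    out: dict[str, float] = {}
    for i, w in enumerate(ROLLING_WINDOWS, start=1):
        lo = _annual_rolling_extreme(grp, w, "min")
        hi = _annual_rolling_extreme(grp, w, "max")
        if lo.empty or hi.empty:
            raise ValueError(f"window {w} d exceeds every retained year's length")
        out[f"DL{i}"] = float(lo.mean())
        out[f"DH{i}"] = float(hi.mean())
    q25, q75 = np.quantile(df["flow"].to_numpy(), [0.25, 0.75])
    _, out["DL16"] = _pulse_stats(df, (df["flow"] < q25).to_numpy())
    _, out["DH15"] = _pulse_stats(df, (df["flow"] > q75).to_numpy())
    zero = (df["flow"] == 0).groupby(df["wy"]).sum()
    days = df["flow"].groupby(df["wy"]).size()
    out["DL18"] = float((zero / days * 365.0).mean())
    return out


def frequency_metrics(series: DailyFlowSeries, start_month: int = 10) -> dict[str, float]:
    """FL1/FH1 pulse counts and FH6/FH7 flood frequencies.

    An event is a maximal run of consecutive qualifying days.
    """
    df = _frame(series, start_month)
    flow = df["flow"].to_numpy()
    q25, q75 = np.quantile(flow, [0.25, 0.75])
    med = float(np.median(flow))
    out: dict[str, float] = {}
    out["FL1"], _ = _pulse_stats(df, flow < q25)
    out["FH1"], _ = _pulse_stats(df, flow > q75)
    out["FH6"], _ = _pulse_stats(df, flow > 3.0 * med)
    out["FH7"], _ = _pulse_stats(df, flow > 7.0 * med)
    return out


def colwell(
    series: DailyFlowSeries,
    n_states: int = 11,
    start_month: int = 10,
) -> tuple[float, float, pd.DataFrame]:
    """Colwell's constancy (C) and predictability (P) of monthly flow states.

    Monthly mean flows are discretised into `n_states` logarithmically spaced
    classes between the positive record min and max; zero months occupy a
    reserved extra state.  With N_ij the count of (state i, month j) cells,
    H(X), H(Y), H(XY) the month / state / joint Shannon entropies:

        C = 1 - H(Y)/log(s),   P = 1 - (H(XY) - H(X))/log(s)

    with s = n_states + 1.  Both lie in [0, 1]; a constant record gives
    C = P = 1.  Returns (C, P, contingency matrix).
    """
    df = _frame(series, start_month)
    monthly = df["flow"].groupby([df["wy"], df["month"]]).mean()
    vals = monthly.to_numpy()
    months = monthly.index.get_level_values(1).to_numpy()
    pos = vals[vals > 0]
    states = np.full(vals.shape, n_states, dtype=int)  # reserved zero state
    if pos.size:
        lo, hi = pos.min(), pos.max()
        if hi > lo:
            edges = np.geomspace(lo, hi, n_states + 1)
            idx = np.searchsorted(edges, vals[vals > 0], side="right") - 1
            states[vals > 0] = np.clip(idx, 0, n_states - 1)
        else:
            states[vals > 0] = 0
    s = n_states + 1
    mat = pd.crosstab(pd.Series(states, name="state"), pd.Series(months, name="month"))
    N = mat.to_numpy(dtype=float)
    total = N.sum()

    def _h(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hx = _h(N.sum(axis=0) / total)
    hy = _h(N.sum(axis=1) / total)
    hxy = _h(N.ravel() / total)
    logs = np.log(s)
    constancy = 1.0 - hy / logs
    predictability = 1.0 - (hxy - hx) / logs
    return float(constancy), float(predictability), mat


def timing_metrics(
    series: DailyFlowSeries, n_states: int = 11, start_month: int = 10
) -> dict[str, float]:
    c, p, _ = colwell(series, n_states=n_states, start_month=start_month)
    return {"TA1": c, "TA2": p}


def rate_metrics(series: DailyFlowSeries, start_month: int = 10) -> dict[str, float]:
    """RA1 rise rate, RA3 fall rate (magnitude), RA8 reversals per year.

    Day-over-day differences are taken within each water year.  A reversal is
    a sign change between consecutive non-zero differences; zero differences
    are transparent.  With no rises (falls) RA1 (RA3) is reported as 0.
    """
    df = _frame(series, start_month)
    rises, falls, reversals = [], [], []
    for _, sub in df["flow"].groupby(df["wy"].to_numpy()):
        d = np.diff(sub.to_numpy())
        rises.extend(d[d > 0])
        falls.extend(-d[d < 0])
        signs = np.sign(d)
        signs = signs[signs != 0]
        reversals.append(
            float((signs[1:] != signs[:-1]).sum()) * 365.0 / len(sub)
        )
    return {
        "RA1": float(np.mean(rises)) if rises else 0.0,
        "RA3": float(np.mean(falls)) if falls else 0.0,
        "RA8": float(np.mean(reversals)) if reversals else 0.0,
    }


def compute_metric_vector(
    series: DailyFlowSeries,
    start_month: int = 10,
    n_states: int = 11,
) -> MetricVector:
    """Union of all index families for a screened record.

    The caller is responsible for screening (see
    :func:`eflow.series.screen_record`); metadata records the number of water
    years present in the series.
    """
    values: dict[str, float] = {}
    values.update(magnitude_metrics(series, start_month))
    values.update(duration_metrics(series, start_month))
    values.update(frequency_metrics(series, start_month))
    values.update(timing_metrics(series, n_states=n_states, start_month=start_month))
    values.update(rate_metrics(series, start_month))
    n_years = len(np.unique(series.water_years(start_month=start_month)))
    return MetricVector(gauge_id=series.gauge_id, values=values, n_years=n_years)
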