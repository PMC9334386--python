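"""Readers and writers for the tabular formats the pipeline touches.

Daily discharge: USGS NWIS RDB (tab-delimited with ``#`` comment header and
a column-type row) and plain CSV (date, discharge).  Tables: UTF-8 comma CSV
with empty cells for missing values; every writer emits a small YAML
manifest alongside the data documenting columns, units and conventions.
Reach identifiers: NHDPlus V1 ids with an optional crosswalk expansion to
V2 ids.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import DailyFlowSeries

__all__ = [
    "read_daily_flow",
    "write_daily_flow",
    "write_table",
    "read_table",
    "crosswalk_comids",
    "save_reference_pca",
    "load_reference_pca",
]

CFS_PER_CMS = 1.0 / 0.0283168466

#: values NWIS uses for unavailable/estimated records
_MISSING_CODES = {"", "ice", "eqp", "dis", "rat", "mnt", "zfl", "***", "-999999"}

_FLOAT_FMT = "%.17g"  # exact float64 round trip, so stages can restart from CSVs


class FlowParseError(ValueError):
    """Unparseable date or negative discharge, with the offending line."""


def _parse_discharge(raw: pd.Series, path: str) -> pd.Series:
    cleaned = raw.astype(str).str.strip()
    missing = cleaned.str.lower().isin(_MISSING_CODES) | cleaned.eq("nan")
    vals = pd.to_numeric(cleaned.where(~missing), errors="coerce")
    bad = vals.isna() & ~missing & cleaned.ne("nan")
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise FlowParseError(f"{path}: unparseable discharge near data row {line}")
    neg = vals < 0
    if neg.any():
        line = int(neg.idxmax()) + 1
        raise FlowParseError(f"{path}: negative discharge at data row {line}")
    return vals


def read_daily_flow(
    path: str | Path,
    dialect: str | None = None,
    units: str = "cfs",
    gauge_id: str | None = None,
    drainage_area_km2: float | None = None,
) -> DailyFlowSeries:
    """Read one gauge's daily discharge record.

    `dialect` is ``"nwis-rdb"`` or ``"csv"``; when omitted it is sniffed
    (an RDB file starts with ``#`` comment lines).  RDB parsing skips the
    comment block and the column-type row, takes the ``datetime`` column and
    the first ``00060``-parameter (discharge) column, and maps NWIS missing
    codes to NaN.  CSV files need (date, discharge) as the first two
    columns.  Feb 29 rows are dropped by the series container.
    """
    path = Path(path)
    text = path.read_text()
    if dialect is None:
        dialect = "nwis-rdb" if text.lstrip().startswith("#") else "csv"
    if dialect == "nwis-rdb":
        lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        if len(lines) < 2:
            raise FlowParseError(f"{path}: no data rows in RDB file")
        df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t", dtype=str)
        df = df.iloc[1:].reset_index(drop=True)  # drop the 5s/20d type row
        date_col = next((c for c in df.columns if "datetime" in c.lower()), None)
        q_col = next(
            (c for c in df.columns if "00060" in c and not c.endswith("_cd")), None
        )
        if date_col is None or q_col is None:
            raise FlowParseError(f"{path}: RDB lacks datetime/00060 columns")
        if gauge_id is None and "site_no" in df.columns:
            gauge_id = str(df["site_no"].iloc[0])
    elif dialect == "csv":
        df = pd.read_csv(path, dtype=str, comment="#")
        date_col, q_col = df.columns[0], df.columns[1]
    else:
        raise ValueError(f"unknown dialect: {dialect}")
    try:
        dates = pd.to_datetime(df[date_col])
    except (ValueError, TypeError) as exc:
        raise FlowParseError(f"{path}: unparseable dates ({exc})") from exc
    flows = _parse_discharge(df[q_col], str(path))
    series = pd.Series(flows.to_numpy(), index=pd.DatetimeIndex(dates))
    return DailyFlowSeries(
        gauge_id=gauge_id or path.stem,
        flows=series,
        units=units,
        drainage_area_km2=drainage_area_km2,
    )


def write_daily_flow(
    series: DailyFlowSeries, path: str | Path, dialect: str = "csv"
) -> None:
    """Write a record as (date, discharge) CSV or a minimal NWIS-RDB file."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "date": series.flows.index.strftime("%Y-%m-%d"),
            "discharge": series.flows.to_numpy(),
        }
    )
    if dialect == "csv":
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif dialect == "nwis-rdb":
        with open(path, "w") as fh:
            fh.write(f"# synthetic daily discharge, gauge {series.gauge_id}\n")
            fh.write(f"# units: {series.units}\n")
            fh.write("site_no\tdatetime\t00060_00003\n")
            fh.write("15s\t20d\t14n\n")
            for d, q in zip(df["date"], df["discharge"]):
                q_txt = "" if pd.isna(q) else _FLOAT_FMT % q
                fh.write(f"{series.gauge_id}\t{d}\t{q_txt}\n")
    else:
        raise ValueError(f"unknown dialect: {dialect}")


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    columns_doc: dict[str, str] | None = None,
    conventions: dict | None = None,
    index: bool = True,
) -> None:
    """Write a CSV plus a ``<name>.manifest.yml`` column dictionary."""
    path = Path(path)
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)
    manifest = {
        "file": path.name,
        "n_rows": int(len(df)),
        "columns": columns_doc or {c: "" for c in df.columns},
        "missing": "empty cell",
        "encoding": "utf-8",
    }
    if conventions:
        manifest["conventions"] = conventions
    with open(path.with_suffix(path.suffix + ".manifest.yml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    # round_trip parsing: restarted stages must see bit-identical floats
    return pd.read_csv(path, index_col=index_col, float_precision="round_trip")


def crosswalk_comids(
    table: pd.DataFrame,
    crosswalk: pd.DataFrame,
    v1_col: str = "comid_v1",
    v2_col: str = "comid_v2",
) -> tuple[pd.DataFrame, dict]:
    """Attach NHDPlus V2 reach ids to a V1-keyed table.

    One-to-many V1 -> V2 matches duplicate the row (``crosswalk_dup`` flag
    set); unmatched V1 ids keep a missing V2 and are counted in the report.
    Exact duplicate (v1, v2) pairs in the crosswalk are a data error.

    Returns (expanded table, report dict).
    """
    dup_pairs = crosswalk.duplicated(subset=[v1_col, v2_col], keep=False)
    if dup_pairs.any():
        offenders = crosswalk.loc[dup_pairs, [v1_col, v2_col]].drop_duplicates()
        raise ValueError(
            f"crosswalk contains duplicate rows: {offenders.to_dict('records')}"
        )
    t = table.reset_index() if table.index.name == v1_col else table.copy()
    merged = t.merge(crosswalk[[v1_col, v2_col]], on=v1_col, how="left")
    counts = merged.groupby(v1_col)[v2_col].transform("count")
    merged["crosswalk_dup"] = counts > 1
    n_unmatched = int(merged[v2_col].isna().sum())
    report = {
        "n_input": int(len(t)),
        "n_output": int(len(merged)),
        "n_unmatched_v1": n_unmatched,
        "n_duplicated_v1": int((counts > 1).sum()),
    }
    return merged, report


def save_reference_pca(pca, directory: str | Path) -> None:
    """Serialize a fitted :class:`eflow.alteration.ReferencePCA` to a
    YAML + CSV bundle reusable across runs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "metrics": list(pca.metrics),
        "k": int(pca.k),
        "eigenvalues": [float(v) for v in pca.eigenvalues],
        "dropped_constant": list(pca.dropped_constant),
        "envelope_classes": sorted(pca.envelopes),
    }
    with open(directory / "pca.yml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    scaling = pd.DataFrame(
        {"col_min": pca.col_min, "col_max": pca.col_max, "mean": pca.mean},
        index=pca.metrics,
    )
    scaling.to_csv(directory / "pca_scaling.csv", float_format=_FLOAT_FMT)
    pd.DataFrame(pca.components, columns=pca.metrics).to_csv(
        directory / "pca_loadings.csv", float_format=_FLOAT_FMT
    )
    env_rows = []
    for cls, env in sorted(pca.envelopes.items()):
        for i, (a, b) in enumerate(env):
            env_rows.append({"class": cls, "component": i + 1, "a": a, "b": b})
    pd.DataFrame(env_rows).to_csv(
        directory / "pca_envelopes.csv", index=False, float_format=_FLOAT_FMT
    )


def load_reference_pca(directory: str | Path):
    from .alteration import ReferencePCA

    directory = Path(directory)
    with open(directory / "pca.yml") as fh:
        meta = yaml.safe_load(fh)
    scaling = pd.read_csv(directory / "pca_scaling.csv", index_col=0)
    loadings = pd.read_csv(directory / "pca_loadings.csv", index_col=0)
    env_df = pd.read_csv(directory / "pca_envelopes.csv")
    envelopes = {}
    for cls, sub in env_df.groupby("class"):
        sub = sub.sort_values("component")
        envelopes[str(cls)] = sub[["a", "b"]].to_numpy()
    return ReferencePCA(
        metrics=meta["metrics"],
        col_min=scaling["col_min"],
        col_max=scaling["col_max"],
        mean=scaling["mean"].to_numpy(),
        components=loadings.to_numpy(),
        eigenvalues=np.asarray(meta["eigenvalues"]),
        k=int(meta["k"]),
        envelopes=envelopes,
        dropped_constant=meta.get("dropped_constant", []),
    )
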