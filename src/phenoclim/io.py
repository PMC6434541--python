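"""Reading and writing the long-format plot tables.

All pipeline inputs and outputs are UTF-8 CSV with ISO-8601 dates. The
readers validate schema and value bounds and resolve plot identifiers
against the experimental design; rows naming unknown plots are rejected
(with a count) rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from hashlib import sha256
from pathlib import Path

import pandas as pd

ENV_COLUMNS = ("plot_id", "timestamp", "canopy_temp_C", "soil_temp_C", "vwc")
NDVI_COLUMNS = ("plot_id", "date", "ndvi")
FLOWERING_COLUMNS = ("plot_id", "species", "date", "open_flowers",
                     "flowering_individuals")


class SchemaError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class ReadReport:
    n_rows: int
    n_rejected_unknown_plot: int


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{what} table missing columns: {sorted(missing)}")


def _resolve_plots(df: pd.DataFrame, design: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    known = set(design["plot_id"])
    mask = df["plot_id"].isin(known)
    return df[mask].copy(), int((~mask).sum())


def _check_monotone(df: pd.DataFrame, time_col: str, what: str) -> None:
    for plot_id, grp in df.groupby("plot_id", sort=False):
        t = grp[time_col].to_numpy()
        if len(t) > 1 and not (t[1:] > t[:-1]).all():
            raise DataError(f"{what}: non-monotone {time_col} in plot {plot_id}")


def read_env_series(path, design: pd.DataFrame,
                    aggregate_daily: bool = True) -> tuple[pd.DataFrame, ReadReport]:
    """Read a datalogger table (plot_id, timestamp, canopy/soil temp, vwc).

    Timestamps must be strictly increasing within each plot and VWC must
    lie in [0, 1]. Sub-daily records are aggregated to daily means before
    any downstream summary (statistics are daily-or-coarser). The returned
    frame has a `date` column (datetime at daily resolution when
    aggregated).
    """
    df = pd.read_csv(path)
    _require_columns(df, ENV_COLUMNS, "environmental")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df, n_rejected = _resolve_plots(df, design)
    bad = df[(df["vwc"] < 0) | (df["vwc"] > 1)]
    if len(bad):
        row = bad.iloc[0]
        raise DataError(
            f"vwc out of [0, 1] for plot {row['plot_id']} at {row['timestamp']} "
            f"(value {row['vwc']})"
        )
    df = df.sort_values(["plot_id", "timestamp"], kind="stable")
    _check_monotone(df, "timestamp", "environmental series")
    if aggregate_daily:
        df["date"] = df["timestamp"].dt.normalize()
        df = (df.groupby(["plot_id", "date"], as_index=False)
                [["canopy_temp_C", "soil_temp_C", "vwc"]].mean())
    else:
        df = df.rename(columns={"timestamp": "date"})
    return df, ReadReport(len(df), n_rejected)


def read_ndvi_series(path, design: pd.DataFrame) -> tuple[pd.DataFrame, ReadReport]:
    """Read per-plot NDVI surveys (plot_id, date, ndvi in [-1, 1])."""
    df = pd.read_csv(path)
    _require_columns(df, NDVI_COLUMNS, "NDVI")
    df["date"] = pd.to_datetime(df["date"])
    df, n_rejected = _resolve_plots(df, design)
    bad = df[(df["ndvi"] < -1) | (df["ndvi"] > 1)]
    if len(bad):
        row = bad.iloc[0]
        raise DataError(f"NDVI out of [-1, 1] for plot {row['plot_id']} at "
                        f"{row['date'].date()} (value {row['ndvi']})")
    df = df.sort_values(["plot_id", "date"], kind="stable")
    _check_monotone(df, "date", "NDVI series")
    return df, ReadReport(len(df), n_rejected)


def read_flowering_surveys(path, design: pd.DataFrame
                           ) -> tuple[pd.DataFrame, ReadReport]:
    """Read flowering surveys (plot_id, species, date, counts >= 0)."""
    df = pd.read_csv(path)
    _require_columns(df, FLOWERING_COLUMNS, "flowering")
    df["date"] = pd.to_datetime(df["date"])
    df, n_rejected = _resolve_plots(df, design)
    for col in ("open_flowers", "flowering_individuals"):
        if (df[col] < 0).any():
            raise DataError(f"negative {col} in flowering surveys")
    df = df.sort_values(["plot_id", "species", "date"], kind="stable")
    return df, ReadReport(len(df), n_rejected)


def read_design(path) -> pd.DataFrame:
    from .design import validate_design, TEMPERATURE_CATEGORY

    df = pd.read_csv(path)
    validate_design(df)
    if "temperature_category" not in df.columns:
        df["temperature_category"] = df["treatment"].map(TEMPERATURE_CATEGORY)
    return df


def exclude_plot_interval(series: pd.DataFrame, plot_id: str,
                          start, end, time_col: str = "date"
                          ) -> tuple[pd.DataFrame, int]:
    """Mask one plot's observations inside [start, end).

    Generic facility for field exclusions such as heater malfunctions (the
    affected interval is supplied in config). All other plots, and the
    plot's observations outside the interval, are untouched. Returns the
    masked frame and the number of rows removed.
    """
    if plot_id not in set(series["plot_id"]):
        raise KeyError(f"unknown plot_id {plot_id!r}")
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end < start:
        raise ValueError(f"malformed interval {start}..{end}")
    t = pd.to_datetime(series[time_col])
    drop = (series["plot_id"] == plot_id) & (t >= start) & (t < end)
    return series[~drop].copy(), int(drop.sum())


def write_table(df: pd.DataFrame, path) -> str:
    """Write a CSV (ISO dates) and return its content digest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d %H:%M:%S").str.replace(
                " 00:00:00", "", regex=False)
        elif out[col].map(lambda x: isinstance(x, date)).any():
            out[col] = out[col].map(lambda x: x.isoformat() if isinstance(x, date) else x)
    out.to_csv(path, index=False)
    return file_digest(path)


def file_digest(path) -> str:
    return sha256(Path(path).read_bytes()).hexdigest()[:12]
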