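"""Readers and writers for the tabular text formats the pipeline consumes.

All inputs and outputs are delimiter-separated text with ISO 8601 dates:
temperature tables (``date,temperature``), optionally sub-daily records with
a ``timestamp`` column, count panels (``year,plot,date,aphids,tillers``),
and the result tables (coefficients, lag curve, AIC profile).  Parse errors
name the offending line.  A converter for a legacy wide spreadsheet layout
(one sheet per year) is provided for old workbook exports.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .phenology import validate_panel
from .thermal import TemperatureSeries, aggregate_daily_means

__all__ = [
    "read_temperature",
    "read_subdaily_temperature",
    "read_counts",
    "read_counts_workbook",
    "write_temperature",
    "write_counts",
    "write_table",
]


def _read_table(path, delimiter: str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True,
                     comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found "
                         f"{list(df.columns)}")
    return df


def _parse_numeric(df: pd.DataFrame, col: str, path, kind=float) -> np.ndarray:
    raw = df[col]
    parsed = pd.to_numeric(raw, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any() or parsed.isna().any():
        i = int((parsed.isna()).idxmax())
        raise ValueError(
            f"{path}, line {i + 2}: cannot parse {col} value {raw.iloc[i]!r}"
        )
    return parsed.to_numpy(dtype=kind)


def _parse_dates(df: pd.DataFrame, col: str, path) -> pd.DatetimeIndex:
    try:
        return pd.DatetimeIndex(pd.to_datetime(df[col], format="ISO8601"))
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        i = int(parsed.isna().idxmax())
        raise ValueError(
            f"{path}, line {i + 2}: cannot parse {col} value {df[col].iloc[i]!r}"
        ) from None


def read_temperature(path, delimiter: str = ",") -> TemperatureSeries:
    """Read a daily temperature table with columns ``date, temperature``."""
    df = _read_table(path, delimiter, ["date", "temperature"])
    dates = _parse_dates(df, "date", path)
    temps = _parse_numeric(df, "temperature", path)
    if dates.has_duplicates:
        dup = dates[dates.duplicated()][0]
        raise ValueError(f"{path}: duplicate date {dup.date()}")
    order = np.argsort(dates)
    return TemperatureSeries(dates[order], temps[order])


def read_subdaily_temperature(
    path, delimiter: str = ",", min_records_per_day: int = 1
) -> TemperatureSeries:
    """Read sub-daily records (``timestamp, temperature``) and aggregate to
    daily means."""
    df = _read_table(path, delimiter, ["timestamp", "temperature"])
    df["temperature"] = _parse_numeric(df, "temperature", path)
    return aggregate_daily_means(df, "timestamp", "temperature",
                                 min_records_per_day=min_records_per_day)


def read_counts(path, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate a count panel (year, plot, date, aphids, tillers)."""
    df = _read_table(path, delimiter, ["year", "plot", "date", "aphids", "tillers"])
    out = pd.DataFrame(
        {
            "year": _parse_numeric(df, "year", path, int),
            "plot": df["plot"].astype(str).str.strip(),
            "date": _parse_dates(df, "date", path),
            "aphids": _parse_numeric(df, "aphids", path, int),
            "tillers": _parse_numeric(df, "tillers", path, int),
        }
    )
    return validate_panel(out)


def read_counts_workbook(path) -> pd.DataFrame:
    """Convert a legacy wide workbook (one sheet per year) to a count panel.

    Assumed layout, enforced loudly: each sheet is named by its four-digit
    year and carries columns plot, date, aphids, tillers.
    """
    sheets = pd.read_excel(path, sheet_name=None)
    frames = []
    for name, df in sheets.items():
        try:
            year = int(str(name).strip())
        except ValueError:
            raise ValueError(
                f"{path}: sheet {name!r} is not a four-digit year; the "
                f"converter expects one sheet per year"
            ) from None
        df.columns = [str(c).strip().lower() for c in df.columns]
        missing = [c for c in ("plot", "date", "aphids", "tillers")
                   if c not in df.columns]
        if missing:
            raise ValueError(f"{path}, sheet {name}: missing column(s) {missing}")
        df = df.assign(year=year)
        frames.append(df[["year", "plot", "date", "aphids", "tillers"]])
    if not frames:
        raise ValueError(f"{path}: workbook has no sheets")
    return validate_panel(pd.concat(frames, ignore_index=True))


def write_temperature(series: TemperatureSeries, path, delimiter: str = ",") -> None:
    pd.DataFrame(
        {"date": series.days.strftime("%Y-%m-%d"), "temperature": series.t_mean}
    ).to_csv(path, sep=delimiter, index=False)


def write_counts(panel: pd.DataFrame, path, delimiter: str = ",") -> None:
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=delimiter, index=False)


def write_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write any result table (records, coefficients, lag curve, profile)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=delimiter, index=False)
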