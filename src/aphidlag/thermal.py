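"""Thermal-time covariates: daily means and degree-day sums over lag windows.

The analysis measures pre-season temperature history through two degree-day
covariates accumulated over the ``L`` days immediately preceding the local
start of the aphid season:

* ``DD5``  — daily mean temperatures on days warmer than 5 °C, the common
  lower developmental threshold for cereal aphids;
* ``DD05`` — daily mean temperatures on days within the closed interval
  [0, 5] °C, the range in which winter wheat develops but aphids do not.

Both are sums of the daily mean temperature itself on qualifying days, which
keeps the two covariates symmetric and disjoint (a day at exactly 5 °C counts
toward DD05 only).  The classical "excess over threshold" form of DD5 is kept
as an explicit mode.  The distributed-lag models additionally need the per-lag
contributions x_1 … x_L whose sum reproduces DD5 on the same window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "LagWindow",
    "aggregate_daily_means",
    "dd5",
    "dd05",
    "lag_contributions",
]

#: Instrument range of the station thermometer; values outside are rejected.
TEMP_MIN = -50.0
TEMP_MAX = 110.0

APHID_THRESHOLD = 5.0
WHEAT_THRESHOLD = 0.0


@dataclass(frozen=True)
class TemperatureSeries:
    """Calendar-indexed daily mean air temperatures (°C).

    Days must be strictly increasing with no duplicates.  Calendar gaps are
    permitted but are recorded in :attr:`missing_days` and never silently
    interpolated: any window computation touching a missing day fails unless
    an explicit tolerance policy is requested.
    """

    days: pd.DatetimeIndex
    t_mean: np.ndarray
    missing_days: pd.DatetimeIndex = field(init=False, repr=False)

    def __post_init__(self) -> None:
        days = pd.DatetimeIndex(self.days).normalize()
        t = np.asarray(self.t_mean, dtype=float)
        if len(days) == 0:
            raise ValueError("temperature series is empty")
        if len(days) != len(t):
            raise ValueError("days and t_mean differ in length")
        if days.has_duplicates:
            dup = days[days.duplicated()][0]
            raise ValueError(f"duplicate date in temperature series: {dup.date()}")
        if not days.is_monotonic_increasing:
            raise ValueError("temperature days must be strictly increasing")
        if not np.all(np.isfinite(t)):
            bad = days[~np.isfinite(t)][0]
            raise ValueError(f"non-finite temperature on {bad.date()}")
        out = (t < TEMP_MIN) | (t > TEMP_MAX)
        if out.any():
            i = int(np.argmax(out))
            raise ValueError(
                f"temperature {t[i]} °C on {days[i].date()} outside instrument "
                f"range [{TEMP_MIN}, {TEMP_MAX}] °C"
            )
        full = pd.date_range(days[0], days[-1], freq="D")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "t_mean", t)
        object.__setattr__(self, "missing_days", full.difference(days))
        object.__setattr__(self, "_contiguous", len(full) == len(days))

    def __len__(self) -> int:
        return len(self.days)

    @property
    def start(self) -> pd.Timestamp:
        return self.days[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.days[-1]

    def as_series(self) -> pd.Series:
        return pd.Series(self.t_mean, index=self.days, name="t_mean")

    def window_values(self, window: "LagWindow", policy: str = "error") -> np.ndarray:
        """Daily means ordered by lag: element ``l-1`` is the day ``anchor − l``.

        ``policy="error"`` (default) refuses windows with missing days;
        ``policy="renormalize"`` returns only the present days (callers rescale).
        """
        anchor = pd.Timestamp(window.anchor_day).normalize()
        first = anchor - pd.Timedelta(days=window.depth_L)
        if first < self.start:
            earliest = self.start + pd.Timedelta(days=window.depth_L)
            raise ValueError(
                f"window of depth {window.depth_L} before {anchor.date()} starts "
                f"{first.date()}, before the record begins {self.start.date()}; "
                f"earliest feasible anchor is {earliest.date()}"
            )
        if anchor - pd.Timedelta(days=1) > self.end:
            raise ValueError(
                f"window before {anchor.date()} ends after the record "
                f"({self.end.date()})"
            )
        # lag l runs 1..L: anchor-1 is lag 1, anchor-L is lag L
        if self._contiguous:
            pos = (anchor - self.start).days  # position anchor would occupy
            lo = pos - window.depth_L
            hi = min(pos, len(self.t_mean))
            vals = np.full(window.depth_L, np.nan)
            vals[pos - hi:] = self.t_mean[lo:hi][::-1]
        else:
            wanted = anchor - pd.to_timedelta(
                np.arange(1, window.depth_L + 1), unit="D"
            )
            vals = self.as_series().reindex(wanted).to_numpy()
        missing = np.isnan(vals)
        if missing.any():
            if policy == "error":
                miss = wanted[missing]
                raise ValueError(
                    f"{missing.sum()} missing day(s) in window before "
                    f"{anchor.date()}, e.g. {miss[0].date()}; pass "
                    f"policy='renormalize' to rescale over present days"
                )
            if policy == "renormalize":
                warnings.warn(
                    f"{missing.sum()} of {window.depth_L} window days missing "
                    f"before {anchor.date()}; renormalizing",
                    stacklevel=2,
                )
                return vals
            raise ValueError(f"unknown missing-day policy {policy!r}")
        return vals

    def covers_window(self, window: "LagWindow") -> bool:
        try:
            self.window_values(window)
        except ValueError:
            return False
        return True


@dataclass(frozen=True)
class LagWindow:
    """The ``depth_L`` consecutive days strictly before ``anchor_day``.

    The anchor (local season start) is excluded; lag 1 is the day immediately
    before the anchor and lag L the most distant day.
    """

    anchor_day: pd.Timestamp
    depth_L: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor_day", pd.Timestamp(self.anchor_day).normalize())
        if int(self.depth_L) < 1:
            raise ValueError("depth_L must be a positive integer")
        object.__setattr__(self, "depth_L", int(self.depth_L))


def aggregate_daily_means(
    records: pd.DataFrame,
    timestamp_col: str = "timestamp",
    temp_col: str = "temperature",
    min_records_per_day: int = 1,
) -> TemperatureSeries:
    """Collapse sub-daily temperature records to daily arithmetic means.

    Days observed with fewer than ``min_records_per_day`` records are emitted
    as missing (a calendar gap in the result) and reported in a warning.
    Out-of-range temperatures are rejected naming the offending record.
    """
    if len(records) == 0:
        raise ValueError("no temperature records to aggregate")
    ts = pd.to_datetime(records[timestamp_col])
    temp = pd.to_numeric(records[temp_col])
    bad = (temp < TEMP_MIN) | (temp > TEMP_MAX) | ~np.isfinite(temp)
    if bad.any():
        i = bad.idxmax()
        raise ValueError(
            f"temperature {temp.loc[i]} at {ts.loc[i]} (row {i}) outside "
            f"instrument range [{TEMP_MIN}, {TEMP_MAX}] °C"
        )
    grouped = temp.groupby(ts.dt.normalize())
    means = grouped.mean()
    counts = grouped.size()
    thin = counts.index[counts < min_records_per_day]
    if len(thin) > 0:
        warnings.warn(
            f"{len(thin)} day(s) with fewer than {min_records_per_day} records "
            f"dropped (first: {thin[0].date()})",
            stacklevel=2,
        )
        means = means.drop(thin)
    if len(means) == 0:
        raise ValueError("no day met the minimum record count")
    return TemperatureSeries(pd.DatetimeIndex(means.index), means.to_numpy())


def _dd5_daily(vals: np.ndarray, mode: str) -> np.ndarray:
    hot = vals > APHID_THRESHOLD
    if mode == "sum-above":
        return np.where(hot, vals, 0.0)
    if mode == "excess":
        return np.where(hot, vals - APHID_THRESHOLD, 0.0)
    raise ValueError(f"unknown dd5 mode {mode!r}; use 'sum-above' or 'excess'")


def dd5(
    series: TemperatureSeries,
    window: LagWindow,
    mode: str = "sum-above",
    policy: str = "error",
) -> float:
    """Degree days above the 5 °C aphid threshold over the window (°C·day).

    Default mode ``"sum-above"`` sums the daily mean itself on days strictly
    above 5 °C; mode ``"excess"`` sums the excess over 5 °C instead.
    """
    vals = series.window_values(window, policy=policy)
    present = np.isfinite(vals)
    total = float(np.nansum(_dd5_daily(vals[present], mode)))
    if present.sum() < window.depth_L:
        total *= window.depth_L / present.sum()
    return total


def dd05(series: TemperatureSeries, window: LagWindow, policy: str = "error") -> float:
    """Degree days within [0, 5] °C (wheat develops, aphids do not), °C·day.

    The interval is closed at both ends; a day at exactly 0 °C satisfies the
    indicator but contributes 0 by value.
    """
    vals = series.window_values(window, policy=policy)
    present = np.isfinite(vals)
    v = vals[present]
    inside = (v >= WHEAT_THRESHOLD) & (v <= APHID_THRESHOLD)
    total = float(np.sum(np.where(inside, v, 0.0)))
    if present.sum() < window.depth_L:
        total *= window.depth_L / present.sum()
    return total


def lag_contributions(
    series: TemperatureSeries,
    window: LagWindow,
    mode: str = "sum-above",
    standardized: bool = False,
) -> np.ndarray:
    """Per-lag DD5 contributions x_1 … x_L (lag 1 = day before the anchor).

    The vector sums to :func:`dd5` on the same window and mode.  With
    ``standardized=True`` each element is divided by L, matching the DD5/L
    standardization used in the regression models.
    """
    vals = series.window_values(window)
    x = _dd5_daily(vals, mode)
    if standardized:
        x = x / window.depth_L
    return x
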