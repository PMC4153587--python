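"""From weekly count panels to plot-season regression rows.

The response of the whole analysis is TSM, the time from the start of the
aphid season to its density maximum: for each (year, plot) the number of days
between the first sampling date with non-zero density (aphids per tiller) and
the date on which the observed density peaks.  Because sampling is weekly,
season starts and TSM are resolved only to the sampling grid; nothing is
interpolated between sampling dates.  Ties in the maximum are broken toward
the earliest date, which makes TSM conservative (shortest).

``build_records`` assembles one row per plot-season: start day, TSM, the
sampling-effort weight n_ij, and the previous-year summaries (mean over plots
of the maximum density, and of TSM) that the regression models use to correct
for internal aphid dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlotSeasonRecord",
    "validate_panel",
    "density_series",
    "tsm_from_series",
    "build_records",
]

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["year", "plot", "date", "aphids", "tillers"]
WEIGHT_RULES = ("total", "mean-per-date", "at-peak")


@dataclass(frozen=True)
class PlotSeasonRecord:
    """One regression row: a (year, plot) season."""

    year: int
    plot: str
    start_day: pd.Timestamp
    tsm: float
    n_weight: float
    prev_max: float  # NaN for the first panel year
    prev_tsm: float  # NaN for the first panel year


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a count panel (year, plot, date, aphids, tillers)."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"count panel missing columns: {missing}")
    out = panel[PANEL_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.normalize()
    out["year"] = out["year"].astype(int)
    out["aphids"] = out["aphids"].astype(int)
    out["tillers"] = out["tillers"].astype(int)
    if (out["tillers"] < 1).any():
        row = out.index[out["tillers"] < 1][0]
        raise ValueError(f"non-positive tiller count at row {row}")
    if (out["aphids"] < 0).any():
        row = out.index[out["aphids"] < 0][0]
        raise ValueError(f"negative aphid count at row {row}")
    dup = out.duplicated(subset=["year", "plot", "date"])
    if dup.any():
        r = out.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate observation for year={r['year']} plot={r['plot']} "
            f"date={r['date'].date()}"
        )
    return out


def density_series(obs: pd.DataFrame) -> pd.Series:
    """Densities (aphids per tiller) for one plot-year, indexed by date."""
    if len(obs) == 0:
        raise ValueError("no observations")
    if (obs["tillers"] <= 0).any():
        raise ValueError("zero or negative tiller count")
    obs = obs.sort_values("date")
    dens = obs["aphids"].to_numpy(dtype=float) / obs["tillers"].to_numpy(dtype=float)
    return pd.Series(dens, index=pd.DatetimeIndex(obs["date"]), name="density")


def tsm_from_series(densities: pd.Series) -> tuple[pd.Timestamp, int]:
    """Season start and time-from-start-to-maximum (days) of a density series.

    Start is the earliest date with non-zero density; TSM the day count from
    start to the (earliest) date attaining the maximum density.
    """
    dens = densities.sort_index()
    nonzero = dens[dens > 0]
    if len(nonzero) == 0:
        raise ValueError("no season detected: all densities are zero")
    start = nonzero.index[0]
    peak_day = nonzero.index[int(np.argmax(nonzero.to_numpy()))]
    return pd.Timestamp(start), int((peak_day - start).days)


def _season_weight(obs: pd.DataFrame, dens: pd.Series, start, rule: str) -> float:
    # effort over the detected season (dates from the first non-zero on)
    in_season = obs["date"] >= start
    tillers = obs.loc[in_season, "tillers"]
    if rule == "total":
        return float(tillers.sum())
    if rule == "mean-per-date":
        return float(tillers.mean())
    if rule == "at-peak":
        season = dens[dens.index >= start]
        peak_day = season.index[int(np.argmax(season.to_numpy()))]
        return float(obs.loc[obs["date"] == peak_day, "tillers"].iloc[0])
    raise ValueError(f"unknown weight rule {rule!r}; use one of {WEIGHT_RULES}")


def build_records(panel: pd.DataFrame, weight_rule: str = "total") -> pd.DataFrame:
    """One regression row per plot-year with a detected season.

    Returns a DataFrame with columns year, plot, start_day, tsm, n_weight,
    max_density, prev_max, prev_tsm.  Previous-year terms are plot-averaged
    summaries of year i−1 and are NaN for the first panel year (such rows are
    excluded, with a logged count, by fits that need them).  Plot-years with
    no non-zero count are skipped and logged.
    """
    panel = validate_panel(panel)
    rows = []
    skipped = 0
    for (year, plot), obs in panel.groupby(["year", "plot"], sort=True):
        dens = density_series(obs)
        try:
            start, tsm = tsm_from_series(dens)
        except ValueError:
            skipped += 1
            continue
        rows.append(
            {
                "year": int(year),
                "plot": plot,
                "start_day": start,
                "tsm": float(tsm),
                "n_weight": _season_weight(obs, dens, start, weight_rule),
                "max_density": float(dens.max()),
            }
        )
    if skipped:
        logger.info("skipped %d plot-year(s) with no detected season", skipped)
    if not rows:
        raise ValueError("no plot-year with a detected season")
    rec = pd.DataFrame(rows)
    yearly = rec.groupby("year").agg(
        year_max=("max_density", "mean"), year_tsm=("tsm", "mean")
    )
    shifted = yearly.set_axis(yearly.index + 1)  # summaries of year i−1, keyed by i
    rec["prev_max"] = rec["year"].map(shifted["year_max"])
    rec["prev_tsm"] = rec["year"].map(shifted["year_tsm"])
    n_first = int(rec["prev_max"].isna().sum())
    if n_first:
        logger.info("%d record(s) lack previous-year terms (first panel year)", n_first)
    return rec
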