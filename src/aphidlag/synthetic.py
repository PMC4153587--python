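"""Synthetic study generator: temperatures, seasons, trajectories, counts.

Emulates the structure of the 24-year winter-wheat aphid study so every
pipeline stage is testable by parameter recovery without the field data:

* a daily temperature series with a sinusoidal seasonal cycle and AR(1)
  day-to-day noise, standing in for the station record;
* per year, 3–6 plots with season starts near day-of-year 143, weekly
  sampling on 50–300 tillers per plot-date over 6–10 weeks;
* TSM generated from the linear model
  ``TSM = μ + β₁·DD5/L + δ·DD05/L + γ·prev + ε`` with ε ~ N(0, σ²/n_ij)
  (or a lag-varying Σ_l β₁ₗ x_l/L term for the distributed-lag truth);
* left-skewed triangular density trajectories (geometric rise to the peak,
  faster geometric decline) sampled as Poisson counts on the tillers.

Two access points: :func:`simulate_records` emits exact Gaussian regression
rows (the model the estimator assumes — used for coverage and recovery
experiments), and :func:`simulate_panel` additionally rounds TSM to the
weekly sampling grid and emits the count panel (used for round-trip and
end-to-end pipeline tests).  Everything is deterministic under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import thermal
from .thermal import LagWindow, TemperatureSeries

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "bimodal_lag_curve",
    "simulate_temperature",
    "simulate_records",
    "simulate_panel",
    "triangular_trajectory",
]


def bimodal_lag_curve(
    L: int,
    depth: float = -35.0,
    centers: tuple[float, float] = (65.0, 100.0),
    widths: tuple[float, float] = (9.0, 6.0),
) -> np.ndarray:
    """Lag-curve preset with two negative windows at lags ~50–80 and ~90–110.

    Gaussian bumps centred at lags 65 and 100; the depth is scaled so the
    curve averages to roughly the homogeneous-model β₁ over L = 123 lags.
    Zero (no temperature effect) away from the bumps.
    """
    lags = np.arange(1, L + 1, dtype=float)
    curve = np.zeros(L)
    for c, s in zip(centers, widths):
        curve += depth * np.exp(-0.5 * ((lags - c) / s) ** 2)
    return curve


@dataclass(frozen=True)
class SyntheticConfig:
    """All true parameters of the data-generating process.

    Defaults are the study conditions: 24 years, up to 6 plots, weekly counts
    on 50–300 tillers over 6–10 weeks, mean season start at day-of-year 143,
    a temperate-continental temperature climatology, and regression truth at
    the scale of the published estimates (β₁ = −15, δ = −20, γ = 0,
    L = 123, residual sd ≈ 6 days at the average sampling effort).
    """

    # panel dimensions
    n_years: int = 24
    first_year: int = 1987
    plots_min: int = 3
    plots_max: int = 6
    # seasonal temperature model (°C): T = mean + A·sin(2π(doy − phase)/365.25)
    temp_mean: float = 9.0
    temp_amplitude: float = 10.0
    temp_phase: float = 109.0  # maximum mid-July, minimum mid-January
    # day-to-day sd 3.5 °C (AR 0.7) matches midlatitude station variability
    # and gives winter thaw days, so even deep-winter lags carry DD5 signal
    temp_noise_sd: float = 3.5
    temp_ar1: float = 0.7
    # regression truth
    mu: float = 140.0
    beta1: float = -15.0
    delta: float = -20.0
    gamma: float = 0.0
    sigma2: float = 50625.0  # Var(ε)=σ²/n; sd ≈ 6 d at n ≈ 1400 tillers
    true_L: int = 123
    lag_curve: np.ndarray | None = None  # per-lag β₁ₗ truth; overrides beta1
    density_term: str = "prev_max"  # which previous-year summary γ multiplies
    dd_mode: str = "sum-above"
    # season phenology and sampling effort
    start_mean_doy: float = 143.0
    start_sd: float = 7.0
    tillers_min: int = 50
    tillers_max: int = 300
    weeks_min: int = 6
    weeks_max: int = 10
    sampling_interval: int = 7
    # peak-density process (aphids/tiller): lognormal year level with AR(1)
    peak_log_mean: float = 2.08  # exp ≈ 8 aphids/tiller
    peak_year_sd: float = 0.9
    peak_year_ar1: float = 0.5
    peak_plot_sd: float = 0.3
    peak_floor: float = 0.3
    # trajectory shape: geometric rise, faster geometric decline (per week)
    rise_factor: float = 2.0
    decline_factor: float = 4.0
    count_noise: str = "poisson"  # or "none" for noiseless densities

    def __post_init__(self) -> None:
        if self.n_years < 1 or self.plots_min < 1 or self.plots_max < self.plots_min:
            raise ValueError("invalid panel dimensions")
        if self.sigma2 < 0 or self.temp_noise_sd < 0 or self.start_sd < 0:
            raise ValueError("variances must be non-negative")
        if not 0 <= self.temp_ar1 < 1 or not 0 <= self.peak_year_ar1 < 1:
            raise ValueError("AR(1) coefficients must lie in [0, 1)")
        if self.decline_factor < self.rise_factor:
            raise ValueError("decline must be at least as fast as the rise")
        if self.density_term not in ("prev_max", "prev_tsm"):
            raise ValueError("density_term must be 'prev_max' or 'prev_tsm'")
        if self.lag_curve is not None:
            lc = np.asarray(self.lag_curve, dtype=float)
            if lc.shape != (self.true_L,):
                raise ValueError("lag_curve must have length true_L")
            object.__setattr__(self, "lag_curve", lc)

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete simulated study: temperatures, counts, and ground truth."""

    temps: TemperatureSeries
    panel: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig = field(repr=False)


def _ar1(rng: np.random.Generator, n: int, marginal_sd: float, phi: float) -> np.ndarray:
    if marginal_sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = marginal_sd * np.sqrt(1.0 - phi**2)
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, marginal_sd)
    return lfilter([1.0], [1.0, -phi], e)


def simulate_temperature(config: SyntheticConfig, seed: int) -> TemperatureSeries:
    """Daily mean temperatures covering two years before the first season.

    T̄ₜ = m + A·sin(2π(doy − φ)/365.25) + εₜ with AR(1) εₜ.  The record
    starts two calendar years before ``first_year`` so that every candidate
    lag window (including profile grids wider than the true L) is covered.
    """
    rng = np.random.default_rng([int(seed), 0xA11D])
    days = pd.date_range(
        f"{config.first_year - 2}-01-01",
        f"{config.first_year + config.n_years - 1}-12-31",
        freq="D",
    )
    doy = days.dayofyear.to_numpy(dtype=float)
    seasonal = config.temp_mean + config.temp_amplitude * np.sin(
        2.0 * np.pi * (doy - config.temp_phase) / 365.25
    )
    noise = _ar1(rng, len(days), config.temp_noise_sd, config.temp_ar1)
    return TemperatureSeries(days, seasonal + noise)


def _lag_effect(config: SyntheticConfig, temps, window) -> float:
    """The DD5 regression term of the linear predictor for one record."""
    if config.lag_curve is None:
        d5 = thermal.dd5(temps, window, mode=config.dd_mode)
        return config.beta1 * d5 / config.true_L
    x = thermal.lag_contributions(temps, window, mode=config.dd_mode,
                                  standardized=True)
    return float(config.lag_curve @ x)


def simulate_records(
    config: SyntheticConfig, seed: int
) -> tuple[TemperatureSeries, pd.DataFrame]:
    """Exact regression rows from the generating model (no grid rounding).

    Returns the temperature series and one row per (year, plot) with columns
    year, plot, start_day, tsm, n_weight, prev_max, prev_tsm plus ground
    truth (dd5, dd05, lin_pred, peak_density).  A burn-in season in
    ``first_year − 1`` supplies previous-year summaries for the first panel
    year, so every emitted row is usable in a fit.
    """
    temps = simulate_temperature(config, seed)
    rng = np.random.default_rng([int(seed), 0x5EED])
    years = np.arange(config.first_year - 1, config.first_year + config.n_years)
    u = _ar1(rng, len(years), config.peak_year_sd, config.peak_year_ar1)
    year_peak_mean = np.exp(config.peak_log_mean + u)

    rows: list[dict] = []
    prev_max = np.nan
    prev_tsm = np.nan
    for yi, year in enumerate(years):
        n_plots = int(rng.integers(config.plots_min, config.plots_max + 1))
        peaks, tsms = [], []
        for p in range(n_plots):
            start_doy = int(round(rng.normal(config.start_mean_doy, config.start_sd)))
            start = pd.Timestamp(year=int(year), month=1, day=1) + pd.Timedelta(
                days=start_doy - 1
            )
            window = LagWindow(start, config.true_L)
            d5 = thermal.dd5(temps, window, mode=config.dd_mode)
            d05 = thermal.dd05(temps, window)
            lag_term = _lag_effect(config, temps, window)
            tillers = int(rng.integers(config.tillers_min, config.tillers_max + 1))
            n_dates = int(rng.integers(config.weeks_min, config.weeks_max + 1))
            n_weight = float(tillers * n_dates)
            prev = prev_max if config.density_term == "prev_max" else prev_tsm
            gamma_term = config.gamma * (0.0 if np.isnan(prev) else prev)
            lin_pred = (
                config.mu + lag_term + config.delta * d05 / config.true_L + gamma_term
            )
            eps = rng.normal(0.0, np.sqrt(config.sigma2 / n_weight))
            tsm = max(lin_pred + eps, 0.0)
            peak = max(
                year_peak_mean[yi] * np.exp(rng.normal(0.0, config.peak_plot_sd)),
                config.peak_floor,
            )
            peaks.append(peak)
            tsms.append(tsm)
            rows.append(
                {
                    "year": int(year),
                    "plot": f"P{p + 1}",
                    "start_day": start,
                    "tsm": tsm,
                    "n_weight": n_weight,
                    "tillers_per_date": tillers,
                    "n_dates": n_dates,
                    "prev_max": prev_max,
                    "prev_tsm": prev_tsm,
                    "dd5": d5,
                    "dd05": d05,
                    "lin_pred": lin_pred,
                    "peak_density": peak,
                }
            )
        prev_max = float(np.mean(peaks))
        prev_tsm = float(np.mean(tsms))

    rec = pd.DataFrame(rows)
    rec = rec[rec["year"] >= config.first_year].reset_index(drop=True)
    if rec["lin_pred"].mean() < 0:
        raise ValueError(
            f"configuration implies negative expected TSM "
            f"(mean linear predictor {rec['lin_pred'].mean():.1f} d); raise mu "
            f"or weaken the temperature effects"
        )
    return temps, rec


def triangular_trajectory(
    start_day,
    tsm: int,
    peak_density: float,
    sampling_dates,
    rise_factor: float = 2.0,
    decline_factor: float = 4.0,
) -> pd.Series:
    """Left-skewed triangular density trajectory on the sampling dates.

    Density rises geometrically from a small positive value at ``start_day``
    to ``peak_density`` exactly at ``start_day + tsm``, then declines at the
    (faster) decline rate; zero before the start.  If the peak does not fall
    on a sampling date it is shifted to the nearest one and the shift is
    recorded in ``result.attrs["peak_shift_days"]``.
    """
    if tsm < 0:
        raise ValueError("tsm must be non-negative")
    if peak_density <= 0:
        raise ValueError("peak density must be positive")
    if rise_factor <= 1 or decline_factor < rise_factor:
        raise ValueError("need decline_factor >= rise_factor > 1")
    dates = pd.DatetimeIndex(sampling_dates).sort_values()
    start = pd.Timestamp(start_day).normalize()
    if start not in dates:
        raise ValueError("start_day must be a sampling date")
    peak_target = start + pd.Timedelta(days=int(tsm))
    shift = (dates - peak_target).days.to_numpy()
    nearest = int(np.argmin(np.abs(shift)))
    peak_day = dates[nearest]
    if peak_day < start:
        raise ValueError("no sampling date at or after the peak")

    days_from_peak = (dates - peak_day).days.to_numpy(dtype=float)
    dens = np.where(
        days_from_peak <= 0,
        peak_density * rise_factor ** (days_from_peak / 7.0),
        peak_density * decline_factor ** (-days_from_peak / 7.0),
    )
    dens[dates < start] = 0.0
    out = pd.Series(dens, index=dates, name="density")
    out.attrs["peak_shift_days"] = int(shift[nearest])
    return out


def simulate_panel(config: SyntheticConfig, seed: int) -> SyntheticDataset:
    """Full synthetic study: weekly count panel plus ground-truth table.

    TSM values from :func:`simulate_records` are rounded to the sampling
    grid, realized as triangular trajectories, and sampled as counts
    (Poisson around density × tillers, or exact when
    ``count_noise == "none"``).  The truth table carries both the latent and
    the grid-rounded TSM; extracting TSM from a noiseless panel recovers the
    rounded value exactly.
    """
    temps, rec = simulate_records(config, seed)
    rng = np.random.default_rng([int(seed), 0xC0437])
    step = int(config.sampling_interval)

    panel_rows: list[dict] = []
    truth_rows: list[dict] = []
    for r in rec.itertuples(index=False):
        n_up = int(round(r.tsm / step))
        tsm_grid = n_up * step
        n_down = max(int(r.n_dates) - n_up - 1, 2)
        dates = pd.date_range(
            r.start_day - pd.Timedelta(days=step),
            periods=n_up + n_down + 2,
            freq=f"{step}D",
        )
        dens = triangular_trajectory(
            r.start_day, tsm_grid, r.peak_density, dates,
            config.rise_factor, config.decline_factor,
        )
        for d, rho in dens.items():
            lam = rho * r.tillers_per_date
            if config.count_noise == "poisson":
                aphids = int(rng.poisson(lam))
            elif config.count_noise == "none":
                aphids = int(max(round(lam), 1)) if rho > 0 else 0
            else:
                raise ValueError(f"unknown count_noise {config.count_noise!r}")
            panel_rows.append(
                {
                    "year": r.year,
                    "plot": r.plot,
                    "date": d,
                    "aphids": aphids,
                    "tillers": r.tillers_per_date,
                }
            )
        truth_rows.append(
            {
                "year": r.year,
                "plot": r.plot,
                "start_day": r.start_day,
                "tsm_true": float(tsm_grid),
                "tsm_latent": r.tsm,
                "dd5": r.dd5,
                "dd05": r.dd05,
                "lin_pred": r.lin_pred,
                "peak_density": r.peak_density,
                "prev_max": r.prev_max,
                "prev_tsm": r.prev_tsm,
                "n_weight": r.n_weight,
            }
        )

    return SyntheticDataset(
        temps=temps,
        panel=pd.DataFrame(panel_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )
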