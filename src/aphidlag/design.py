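"""Regression design matrices for the four TSM models.

All four models regress TSM_ij on pre-season thermal history with
heteroscedastic errors, Var(ε_ij) = σ²/n_ij:

* model 1:  TSM = μ + β₁·DD5/L + δ·DD05/L + γ·(previous-year max density) + ε
* model 2:  as 1 but correcting with the previous-year TSM instead
* model 3:  the DD5 term is distributed over lags, Σ_l β₁ₗ·x_l/L, with the
  lag curve β₁ₗ constrained to a B-spline basis of K+1 functions
  (an Almon-type distributed lag); previous-year max density correction
* model 4:  as 3 with the previous-year TSM correction

The B-spline restriction β₁ₗ = Σ_k θ_k b_k(l) is what makes the lag-varying
coefficient identifiable from L ≫ K observations of highly collinear daily
temperatures.  With K = 0 and degree 0 the basis is a single constant column
and model 3 collapses algebraically to model 1.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import BSpline

from . import thermal
from .thermal import LagWindow, TemperatureSeries

__all__ = ["LagBasis", "DesignSpec", "DesignMatrices", "bspline_lag_basis", "build_design"]

logger = logging.getLogger(__name__)

#: models correcting with previous-year maximum density vs previous-year TSM
DENSITY_TERM = {1: "prev_max", 2: "prev_tsm", 3: "prev_max", 4: "prev_tsm"}
LAG_VARYING = {1: False, 2: False, 3: True, 4: True}


@dataclass(frozen=True)
class LagBasis:
    """B-spline basis b_0 … b_K evaluated at integer lags 1 … L.

    ``B[l-1, k] = b_k(l)``; rows sum to 1 (partition of unity, full-multiplicity
    boundary knots) and B has full column rank for L > K.
    """

    depth_L: int
    K: int
    degree: int
    knots: np.ndarray
    B: np.ndarray

    def curve(self, theta: np.ndarray) -> np.ndarray:
        """Lag curve β₁ₗ = Σ_k θ_k b_k(l) at lags 1 … L."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.K + 1,):
            raise ValueError(f"theta must have length K+1 = {self.K + 1}")
        return self.B @ theta


def bspline_lag_basis(L: int, K: int = 9, degree: int = 3) -> LagBasis:
    """B-spline lag basis with exactly K+1 functions on lags 1 … L.

    Interior knots are equally spaced on [1, L]; boundary knots have full
    multiplicity, so the basis is a partition of unity.  Requires
    L > K ≥ degree ≥ 0 (fewer lags than basis functions is unidentifiable).
    """
    L, K, degree = int(L), int(K), int(degree)
    if degree < 0 or K < degree:
        raise ValueError(f"need K >= degree >= 0, got K={K}, degree={degree}")
    if L <= K:
        raise ValueError(f"lag basis unidentifiable: need L > K, got L={L}, K={K}")
    n_interior = K - degree
    interior = np.linspace(1.0, float(L), n_interior + 2)[1:-1]
    knots = np.r_[[1.0] * (degree + 1), interior, [float(L)] * (degree + 1)]
    lags = np.arange(1, L + 1, dtype=float)
    B = BSpline.design_matrix(lags, knots, degree).toarray()
    assert B.shape == (L, K + 1)
    return LagBasis(depth_L=L, K=K, degree=degree, knots=knots, B=B)


@dataclass(frozen=True)
class DesignSpec:
    """Which model to build and with what lag depth, basis, and weights."""

    model_id: int
    depth_L: int
    dd_mode: str = "sum-above"
    K: int = 9
    degree: int = 3
    weight_rule: str = "total"
    weight_exponent: float = 1.0  # w = n ** nu in Var(ε) = σ²/n^nu

    def __post_init__(self) -> None:
        if self.model_id not in DENSITY_TERM:
            raise ValueError(f"model_id must be one of 1–4, got {self.model_id}")
        if int(self.depth_L) < 1:
            raise ValueError("depth_L must be positive")
        object.__setattr__(self, "depth_L", int(self.depth_L))

    @property
    def density_term(self) -> str:
        return DENSITY_TERM[self.model_id]

    @property
    def lag_varying(self) -> bool:
        return LAG_VARYING[self.model_id]

    def with_L(self, L: int) -> "DesignSpec":
        d = asdict(self)
        d["depth_L"] = int(L)
        return DesignSpec(**d)

    def basis(self) -> LagBasis | None:
        if not self.lag_varying:
            return None
        return bspline_lag_basis(self.depth_L, self.K, self.degree)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["model"] = d.pop("model_id")
        d["L"] = d.pop("depth_L")
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DesignSpec":
        d = yaml.safe_load(io.StringIO(text))
        d["model_id"] = d.pop("model")
        d["depth_L"] = d.pop("L")
        return cls(**d)


@dataclass(frozen=True)
class DesignMatrices:
    """Response, design matrix, weights and bookkeeping for one fit."""

    y: np.ndarray
    X: np.ndarray
    w: np.ndarray
    names: list[str]
    spec: DesignSpec
    basis: LagBasis | None
    records: pd.DataFrame = field(repr=False)


def _coef_names(spec: DesignSpec) -> list[str]:
    gamma = "gamma_prev_max" if spec.density_term == "prev_max" else "gamma_prev_tsm"
    if spec.lag_varying:
        thetas = [f"theta_{k}" for k in range(spec.K + 1)]
        return ["mu", *thetas, "delta", gamma]
    return ["mu", "beta1", "delta", gamma]


def build_design(
    records: pd.DataFrame,
    temps: TemperatureSeries,
    spec: DesignSpec,
) -> DesignMatrices:
    """Assemble (y, X, w) for the requested model from regression rows.

    ``records`` needs columns year, plot, start_day, tsm, n_weight and the
    previous-year summary the model uses (prev_max or prev_tsm); rows missing
    that summary (the first panel year) are excluded with a logged count.
    Columns are standardized by 1/L only, so coefficients are in °C⁻¹·day
    units directly comparable across L.
    """
    term = spec.density_term
    usable = records[records[term].notna()].reset_index(drop=True)
    dropped = len(records) - len(usable)
    if dropped:
        logger.info("excluded %d record(s) missing %s", dropped, term)
    if len(usable) == 0:
        raise ValueError(f"no records with {term} available")

    L = spec.depth_L
    y = usable["tsm"].to_numpy(dtype=float)
    w = usable["n_weight"].to_numpy(dtype=float) ** spec.weight_exponent
    if np.any(w <= 0):
        raise ValueError("non-positive sampling weight")

    dd05_std = np.empty(len(usable))
    windows = [LagWindow(d, L) for d in usable["start_day"]]
    for i, win in enumerate(windows):
        dd05_std[i] = thermal.dd05(temps, win) / L
    dens = usable[term].to_numpy(dtype=float)
    ones = np.ones(len(usable))

    basis = spec.basis()
    if spec.lag_varying:
        Z = np.empty((len(usable), L))
        for i, win in enumerate(windows):
            Z[i] = thermal.lag_contributions(temps, win, mode=spec.dd_mode,
                                             standardized=True)
        X = np.column_stack([ones, Z @ basis.B, dd05_std, dens])
    else:
        dd5_std = np.array(
            [thermal.dd5(temps, win, mode=spec.dd_mode) for win in windows]
        ) / L
        X = np.column_stack([ones, dd5_std, dd05_std, dens])

    return DesignMatrices(
        y=y, X=X, w=w, names=_coef_names(spec), spec=spec, basis=basis,
        records=usable,
    )
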