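"""Weighted least-squares estimation, AIC-profiled lag depth, and inference.

Estimation follows the Gaussian heteroscedastic model: conditionally on the
covariates, TSM_ij is normal with variance σ²/n_ij, so observations backed by
more inspected tillers carry more weight.  With fixed known weights the IRWLS
fixed point is a single weighted least-squares solve; the iteration is kept
(tolerance 1e-10 on coefficient change, 50 iterations max) as the general
path.

The lag depth L is a structural parameter: it is profiled out by refitting
the model at every candidate L on a common record set and picking the AIC
minimum (ties toward smaller L).  AIC uses the full Gaussian log-likelihood —
2π constant, Σ log wᵢ weight terms, ML variance — with k = p + 1 parameters
(σ² counted), so AIC differences are comparable across models 1–4 on the
same records.  Absolute AIC values depend on these conventions and are not
comparable across software; AIC *differences* are.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrices, DesignSpec, LagBasis, build_design
from .thermal import LagWindow, TemperatureSeries

__all__ = [
    "FitResult",
    "LagProfile",
    "LagCurve",
    "WaldTest",
    "wls_fit",
    "fit_model",
    "profile_L",
    "lag_curve",
    "joint_dd5_test",
    "fit_random_year_gls",
    "compare_models",
    "fit_table",
]

logger = logging.getLogger(__name__)

IRWLS_TOL = 1e-10
IRWLS_MAX_ITER = 50


@dataclass(frozen=True)
class FitResult:
    """Coefficients, covariance and goodness-of-fit of one model fit."""

    params: pd.Series
    cov: pd.DataFrame
    sigma2: float  # unbiased residual scale, weighted RSS / (n − p)
    sigma2_ml: float  # ML scale, weighted RSS / n (inside the likelihood)
    loglik: float
    aic: float
    r2_adj: float  # on the weighted scale (default report)
    r2_adj_unweighted: float
    n_obs: int
    n_params: int  # mean parameters p; AIC uses p + n_variance_params
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    spec: DesignSpec | None = None
    basis: LagBasis | None = None
    design: DesignMatrices | None = field(default=None, repr=False)
    method: str = "wls"
    extra: dict = field(default_factory=dict, repr=False)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index,
                         name="se")

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided p-values from t(n − p)."""
        dof = self.n_obs - self.n_params
        t = self.params / self.se
        return pd.Series(2.0 * stats.t.sf(np.abs(t), dof), index=self.params.index,
                         name="pvalue")

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Per-coefficient confidence intervals from t(n − p)."""
        dof = self.n_obs - self.n_params
        tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
        se = self.se
        return pd.DataFrame(
            {"lower": self.params - tcrit * se, "upper": self.params + tcrit * se}
        )

    @property
    def theta(self) -> pd.Series:
        """Spline coefficients θ₀ … θ_K (lag-varying models only)."""
        mask = self.params.index.str.startswith("theta_")
        if not mask.any():
            raise ValueError("fit has no spline coefficient block")
        return self.params[mask]

    def theta_cov(self) -> np.ndarray:
        mask = self.cov.index.str.startswith("theta_")
        return self.cov.loc[mask, mask].to_numpy()


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate dependent columns from the pivoted QR diagonal
        _, R, piv = _qr_pivot(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [names[j] for j in piv[len(diag):]]
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {X.shape[1]}; collinear column(s): {bad}"
        )


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def _gaussian_loglik(n: int, rss_w: float, w: np.ndarray) -> tuple[float, float]:
    """Profile log-likelihood at the ML variance, with all constants.

    Model: y_i ~ N(x_i'β, σ²/w_i).  Returns (loglik, σ²_ML)."""
    sigma2_ml = rss_w / n
    ll = -0.5 * n * np.log(2.0 * np.pi * sigma2_ml) + 0.5 * np.sum(np.log(w)) - 0.5 * n
    return float(ll), float(sigma2_ml)


def _r2_adj(y: np.ndarray, resid: np.ndarray, w: np.ndarray | None, p: int) -> float:
    n = len(y)
    if w is None:
        rss = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
    else:
        rss = float(w @ resid**2)
        ybar = float(np.average(y, weights=w))
        tss = float(w @ (y - ybar) ** 2)
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def wls_fit(
    y: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    names: list[str] | None = None,
) -> FitResult:
    """Weighted least squares by IRWLS (fixed weights: one reweighted solve).

    Minimizes Σ wᵢ(yᵢ − xᵢ'β)²; SE covariance is σ̂²(XᵀWX)⁻¹ with
    σ̂² = weighted RSS / (n − p).  Coefficients are invariant to rescaling w.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    w = np.asarray(w, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    _check_rank(X, names)

    sw = np.sqrt(w)
    Xs = X * sw[:, None]
    ys = y * sw
    beta = np.zeros(p)
    for _ in range(IRWLS_MAX_ITER):
        beta_new, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        if np.max(np.abs(beta_new - beta)) < IRWLS_TOL:
            beta = beta_new
            break
        beta = beta_new

    fitted = X @ beta
    resid = y - fitted
    rss_w = float(w @ resid**2)
    sigma2 = rss_w / (n - p)
    XtWX = Xs.T @ Xs
    cov = sigma2 * np.linalg.inv(XtWX)
    ll, sigma2_ml = _gaussian_loglik(n, rss_w, w)
    aic = -2.0 * ll + 2.0 * (p + 1)

    return FitResult(
        params=pd.Series(beta, index=names, name="estimate"),
        cov=pd.DataFrame(cov, index=names, columns=names),
        sigma2=sigma2,
        sigma2_ml=sigma2_ml,
        loglik=ll,
        aic=aic,
        r2_adj=_r2_adj(y, resid, w, p),
        r2_adj_unweighted=_r2_adj(y, resid, None, p),
        n_obs=n,
        n_params=p,
        fitted=fitted,
        residuals=resid,
    )


def fit_model(
    records: pd.DataFrame,
    temps: TemperatureSeries,
    spec: DesignSpec,
) -> FitResult:
    """Fit one of models 1–4: build the design and run weighted least squares."""
    dm = build_design(records, temps, spec)
    res = wls_fit(dm.y, dm.X, dm.w, dm.names)
    return replace(res, spec=spec, basis=dm.basis, design=dm)


@dataclass(frozen=True)
class LagProfile:
    """AIC as a function of the candidate lag depth L."""

    L_values: np.ndarray
    aic: np.ndarray
    best_L: int
    n_records: int
    fits: dict[int, FitResult] = field(default_factory=dict, repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"L": self.L_values, "aic": self.aic})


def profile_L(
    records: pd.DataFrame,
    temps: TemperatureSeries,
    spec_template: DesignSpec,
    L_grid,
    keep_fits: bool = False,
) -> LagProfile:
    """Profile the lag depth: refit at every L on a common record set.

    Records are restricted to those whose window is covered by the
    temperature record at the *largest* candidate L, so the AICs along the
    grid are computed on identical observations and remain comparable.
    Candidate L values that no record supports are dropped with a log entry.
    The minimum-AIC L is returned, ties broken toward smaller L.
    """
    grid = sorted({int(L) for L in L_grid})
    if not grid or grid[0] < 1:
        raise ValueError("L grid must contain positive integers")

    usable = records[records[spec_template.density_term].notna()]
    while grid:
        L_max = grid[-1]
        ok = usable["start_day"].map(
            lambda d: temps.covers_window(LagWindow(d, L_max))
        )
        if ok.any():
            break
        logger.info("dropping infeasible L=%d from profile grid", L_max)
        grid = grid[:-1]
    if not grid:
        raise ValueError("no feasible L in the profile grid")
    kept = usable[ok]
    if len(kept) < len(usable):
        logger.info(
            "profiling on %d of %d records (windows at L=%d not covered "
            "for the rest)", len(kept), len(usable), grid[-1],
        )

    aics = np.full(len(grid), np.nan)
    fits: dict[int, FitResult] = {}
    for i, L in enumerate(grid):
        try:
            res = fit_model(kept, temps, spec_template.with_L(L))
        except np.linalg.LinAlgError as e:
            # e.g. DD05 identically zero on a short all-warm window: the
            # model is unidentifiable at this L, so the candidate is dropped
            logger.info("dropping L=%d from profile: %s", L, e)
            continue
        aics[i] = res.aic
        if keep_fits:
            fits[L] = res
    if np.isnan(aics).all():
        raise ValueError("model unidentifiable at every candidate L")
    best = int(np.array(grid)[int(np.nanargmin(aics))])  # first min = smallest L
    return LagProfile(
        L_values=np.asarray(grid), aic=aics, best_L=best, n_records=len(kept),
        fits=fits,
    )


@dataclass(frozen=True)
class LagCurve:
    """The fitted lag-coefficient curve β₁ₗ with pointwise 95% bounds."""

    lags: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag": self.lags, "estimate": self.estimate, "se": self.se,
             "lower": self.lower, "upper": self.upper}
        )

    def local_minima(self) -> np.ndarray:
        """Lags of interior local minima of the curve, deepest first.

        Used to locate the windows of strongest (most negative) temperature
        influence; plateau ties resolve to the leftmost lag."""
        e = self.estimate
        is_min = (e[1:-1] < e[:-2]) & (e[1:-1] <= e[2:])
        lags = self.lags[1:-1][is_min]
        return lags[np.argsort(e[lags - 1])]


Z_95 = float(stats.norm.ppf(0.975))


def lag_curve(fit: FitResult, basis: LagBasis | None = None) -> LagCurve:
    """β̂₁ₗ = Σ_k θ̂_k b_k(l) with pointwise asymptotic 95% confidence bands.

    Pointwise variance is b(l)ᵀ Cov(θ̂) b(l); bounds are estimate ± 1.96·SE.
    """
    if basis is None:
        basis = fit.basis
    if basis is None:
        raise ValueError("no lag basis available; fit models 3 or 4")
    theta = fit.theta.to_numpy()
    if len(theta) != basis.K + 1:
        raise ValueError(
            f"basis has {basis.K + 1} functions but fit has {len(theta)} theta(s)"
        )
    est = basis.B @ theta
    var = np.einsum("lk,km,lm->l", basis.B, fit.theta_cov(), basis.B)
    se = np.sqrt(np.maximum(var, 0.0))
    return LagCurve(
        lags=np.arange(1, basis.depth_L + 1),
        estimate=est,
        se=se,
        lower=est - Z_95 * se,
        upper=est + Z_95 * se,
    )


@dataclass(frozen=True)
class WaldTest:
    statistic: float
    pvalue: float
    df1: int
    df2: int | None
    distribution: str


def joint_dd5_test(fit: FitResult, distribution: str = "f") -> WaldTest:
    """Wald test of no DD5 effect at any lag: θ₀ = … = θ_K = 0.

    The quadratic form θ̂ᵀCov(θ̂)⁻¹θ̂ is referred, divided by K+1, to
    F(K+1, n−p) by default (small samples); ``distribution="chi2"`` uses the
    asymptotic χ²_{K+1} reference on the undivided form.
    """
    theta = fit.theta.to_numpy()
    C = fit.theta_cov()
    try:
        from scipy.linalg import cho_factor, cho_solve

        quad = float(theta @ cho_solve(cho_factor(C), theta))
    except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(f"singular theta covariance: {e}") from e
    q = len(theta)
    dof = fit.n_obs - fit.n_params
    if distribution == "f":
        stat = quad / q
        p = float(stats.f.sf(stat, q, dof))
        return WaldTest(stat, p, q, dof, "f")
    if distribution == "chi2":
        p = float(stats.chi2.sf(quad, q))
        return WaldTest(quad, p, q, None, "chi2")
    raise ValueError(f"unknown distribution {distribution!r}")


def _moment_variance_components(
    resid: np.ndarray, w: np.ndarray, years: np.ndarray
) -> tuple[float, float]:
    """Method-of-moments (τ², σ²) from WLS residuals.

    Model: ε_ij = a_i + e_ij with a_i ~ N(0, τ²) shared within year and
    e_ij ~ N(0, σ²/w_ij); cross products within a year estimate τ²."""
    cross, npairs = 0.0, 0
    for yr in np.unique(years):
        r = resid[years == yr]
        if len(r) > 1:
            s = r.sum()
            cross += 0.5 * (s * s - (r * r).sum())
            npairs += len(r) * (len(r) - 1) // 2
    tau2 = max(cross / npairs, 0.0) if npairs else 0.0
    sigma2 = float(np.mean(w * np.maximum(resid**2 - tau2, 0.0)))
    return tau2, max(sigma2, 1e-12)


def fit_random_year_gls(
    records: pd.DataFrame,
    temps: TemperatureSeries,
    spec: DesignSpec,
    tau2: float | None = None,
) -> FitResult:
    """Sensitivity fit with random year effects (exchangeable within-year
    correlation among plots) on top of the σ²/n_ij variance weights.

    Marginal covariance per year block: Σ = τ²J + σ²·diag(1/w).  τ² and σ²
    are method-of-moments estimates from the WLS residuals unless ``tau2`` is
    given (``tau2=0`` reproduces plain WLS exactly; so does a panel with a
    single plot per year, where τ² is inestimable and set to 0).  Coefficient
    covariance is φ̂·(XᵀΣ⁻¹X)⁻¹ with the whitened residual scale
    φ̂ = RSS/(n−p).
    """
    dm = build_design(records, temps, spec)
    base = wls_fit(dm.y, dm.X, dm.w, dm.names)
    years = dm.records["year"].to_numpy()

    if tau2 is None:
        tau2_hat, sigma2_hat = _moment_variance_components(
            base.residuals, dm.w, years
        )
    else:
        tau2_hat = float(tau2)
        if tau2_hat < 0:
            warnings.warn("tau2 < 0 clipped to 0", stacklevel=2)
            tau2_hat = 0.0
        sigma2_hat = float(np.mean(dm.w * np.maximum(base.residuals**2 - tau2_hat, 0.0)))
        sigma2_hat = max(sigma2_hat, 1e-12)

    n, p = dm.X.shape
    # whiten block by block: Sigma_year = tau2 * J + sigma2 * diag(1/w)
    Xw = np.empty_like(dm.X)
    yw = np.empty_like(dm.y)
    logdet = 0.0
    for yr in np.unique(years):
        idx = np.where(years == yr)[0]
        Sig = tau2_hat * np.ones((len(idx), len(idx))) + np.diag(
            sigma2_hat / dm.w[idx]
        )
        evals, evecs = np.linalg.eigh(Sig)
        logdet += float(np.sum(np.log(evals)))
        root_inv = evecs @ np.diag(evals**-0.5) @ evecs.T
        Xw[idx] = root_inv @ dm.X[idx]
        yw[idx] = root_inv @ dm.y[idx]

    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    fitted = dm.X @ beta
    resid = dm.y - fitted
    rw = yw - Xw @ beta
    rss_white = float(rw @ rw)
    phi = rss_white / (n - p)
    cov = phi * np.linalg.inv(Xw.T @ Xw)

    # Gaussian log-likelihood at the ML scale phi_ml = rss_white / n
    phi_ml = rss_white / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * phi_ml) + logdet + n)
    n_var = 1 if tau2 is not None else 2  # (sigma2) or (sigma2, tau2)
    aic = -2.0 * ll + 2.0 * (p + n_var)

    med_w = float(np.median(dm.w))
    rho = tau2_hat / (tau2_hat + sigma2_hat / med_w) if tau2_hat > 0 else 0.0
    if not 0.0 <= rho < 1.0:  # pragma: no cover - clipped upstream
        warnings.warn(f"estimated within-year correlation {rho:.3f} clipped",
                      stacklevel=2)
        rho = min(max(rho, 0.0), 1.0 - 1e-9)

    return FitResult(
        params=pd.Series(beta, index=dm.names, name="estimate"),
        cov=pd.DataFrame(cov, index=dm.names, columns=dm.names),
        sigma2=sigma2_hat,
        sigma2_ml=phi_ml,
        loglik=ll,
        aic=aic,
        r2_adj=_r2_adj(dm.y, resid, dm.w, p),
        r2_adj_unweighted=_r2_adj(dm.y, resid, None, p),
        n_obs=n,
        n_params=p,
        fitted=fitted,
        residuals=resid,
        spec=spec,
        basis=dm.basis,
        design=dm,
        method="gls-random-year",
        extra={"tau2": tau2_hat, "rho": rho},
    )


def compare_models(fits: list[FitResult], labels: list[str] | None = None) -> pd.DataFrame:
    """Rank fits by AIC.  All fits must share the same record set (n_obs)."""
    if not fits:
        raise ValueError("no fits to compare")
    n0 = fits[0].n_obs
    if any(f.n_obs != n0 for f in fits):
        raise ValueError(
            f"fits computed on different record counts "
            f"{[f.n_obs for f in fits]}; AICs are not comparable"
        )
    if labels is None:
        labels = [
            f"model {f.spec.model_id}" if f.spec is not None else f"fit {i}"
            for i, f in enumerate(fits)
        ]
    tab = pd.DataFrame(
        {
            "model": labels,
            "aic": [f.aic for f in fits],
            "r2_adj": [f.r2_adj for f in fits],
            "n_params": [f.n_params for f in fits],
            "n_obs": [f.n_obs for f in fits],
        }
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].iloc[0]
    return tab[["model", "aic", "delta_aic", "r2_adj", "n_params", "n_obs"]]


def fit_table(fit: FitResult, include_intercept: bool = False) -> pd.DataFrame:
    """Coefficient table (Coefficient, Estimate, Standard error, p-value)."""
    tab = pd.DataFrame(
        {
            "Coefficient": fit.params.index,
            "Estimate": fit.params.to_numpy(),
            "Standard error": fit.se.to_numpy(),
            "p-value": fit.pvalues.to_numpy(),
        }
    )
    if not include_intercept:
        tab = tab[tab["Coefficient"] != "mu"].reset_index(drop=True)
    return tab
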