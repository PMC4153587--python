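# Methods

`aphidlag` estimates how pre-season temperature history regulates the length
of the cereal-aphid population-growth period on winter wheat. This note
records the statistical model, the conventions the implementation fixes
where the method leaves them open, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Response and covariates

**TSM** (time from start to maximum) is, for each year `i` and plot `j`, the
number of days between the first sampling date with non-zero aphid density
(aphids per tiller) and the date the observed density peaks. Sampling is
weekly, so starts and TSM are resolved only to the sampling grid; nothing is
interpolated. Ties in the maximum break toward the *earliest* date, making
TSM conservative. A plot-year with no non-zero count has no season and is
skipped.

**Degree days.** Over the `L` days strictly before the local season start
(lag 1 = the day before the start, lag `L` the most distant; the start day
itself is excluded):

- `DD5` = Σ T̄ₜ · I[T̄ₜ > 5 °C] — thermal time available to aphids,
- `DD05` = Σ T̄ₜ · I[0 ≤ T̄ₜ ≤ 5 °C] — the range in which wheat develops
  but aphids do not.

Both sum the daily mean itself on qualifying days. The phrase "sum of daily
temperatures above 5 °C" could also mean the classical excess T̄ₜ − 5; the
sum-of-temperatures reading is the default because DD05 ("within [0, 5]")
only makes sense that way and the two covariates are treated symmetrically.
The excess form is available as `mode="excess"`. The boundary day at exactly
5 °C belongs to DD05 only (strict `>` for DD5, closed interval for DD05), so
the covariates are disjoint. Days missing from the temperature record are an
error by default; an explicit `renormalize` policy rescales by
L/(days present) with a warning. Both covariates enter the regressions
standardized by 1/L.

## The four models

With ε_ij independent N(0, σ²/n_ij), n_ij the tillers inspected over the
plot-season (sampling effort = information):

1. `TSM_ij = μ + β₁·DD5_ij/L + δ·DD05_ij/L + γ·M̄_{i−1} + ε_ij`, where
   M̄_{i−1} is the previous-year maximum density averaged over plots;
2. as (1) with the previous-year plot-averaged TSM in place of M̄_{i−1};
3. as (1) but distributed over lags: the DD5 term becomes Σ_l β₁ₗ·x_{ijl}/L
   with x_{ijl} the day-at-lag-l contribution (Σ_l x_{ijl} = DD5_ij), and
   β₁ₗ = Σ_k θ_k b_k(l) constrained to K+1 = 10 B-spline basis functions —
   an Almon-type distributed lag;
4. as (3) with the previous-year-TSM correction.

Biological expectations: β₁ < 0 and δ < 0 (warm pre-season days, and days
in [0, 5] °C, both shorten the growth period), γ ≥ 0 if density dependence
exists at all.

**Spline details the method leaves open.** Only the basis family (B-splines)
and K = 9 are prescribed. This package uses cubic splines with
full-multiplicity boundary knots at lags 1 and L and K − degree interior
knots equally spaced on [1, L]; rows of the basis matrix then sum to one
(partition of unity) and the basis has full column rank for L > K. Degree
and knot placement are exposed (`DesignSpec.degree`, `K`) and sensitivity to
them should be reported, not assumed away. With K = 0 and degree 0 the basis
is a single constant column and model 3 reduces *algebraically* to model 1 —
a degeneracy the tests verify to 1e-10.

**Lag indexing.** The coefficient list is sometimes written β₁₀ … β₁L (L+1
values) while the window has L days; this package uses exactly L lags,
1 … L, one per window day.

## Estimation and inference

Parameters are estimated by iteratively reweighted least squares; with the
weights fixed and known (w_ij = n_ij, or n^ν via `weight_exponent`) the
fixed point is a single weighted least-squares solve, and the iteration
(tolerance 1e-10, max 50) converges immediately. Coefficient covariance is
σ̂²(XᵀWX)⁻¹ with σ̂² = weighted RSS/(n − p); p-values are two-sided from
t(n − p), appropriate at n ≈ 140. Rank-deficient designs raise an error
naming the collinear columns rather than silently pseudo-inverting.

**AIC.** The full Gaussian log-likelihood — 2π constant, ½Σ log w_i weight
terms, ML variance RSS_w/n — with k = p + 1 (σ² counted). This makes AIC
differences comparable across models 1–4 on identical records. Absolute AIC
values are convention-dependent across software; only differences are
meaningful here.

**R²_adj** is reported on the weighted scale by default (the unweighted
version is also computed), since the estimator minimizes the weighted sum of
squares; which scale a given software reports is a known ambiguity.

**Profiling L.** The lag depth is structural and not orthogonal to the other
parameters, so it is profiled: the model is refit at every candidate integer
L and the AIC minimum selected, ties toward smaller L (parsimony of history
depth). To keep AICs comparable, all candidates are fit on the *same*
records — those whose window is covered by the temperature record at the
largest candidate L. Candidates at which the model is unidentifiable (e.g. a
short all-warm window makes DD05 identically zero, or a deep-winter spline
column has no above-threshold day) are dropped with a log entry.

**Joint DD5 test.** H₀: θ₀ = … = θ_K = 0 by Wald quadratic form
θ̂ᵀCov(θ̂)⁻¹θ̂, divided by K+1 and referred to F(K+1, n−p) (exact under the
Gaussian model; a χ²_{K+1} version is available).

**Lag curve.** β̂₁ₗ = Σ_k θ̂_k b_k(l) with pointwise variance
b(l)ᵀCov(θ̂)b(l) and asymptotic 95% bounds ±1.96·SE. Bands widen sharply at
the most distant lags, where few winter days exceed 5 °C and the spline
columns have little support — the same behaviour seen in field data.

**Random-year sensitivity.** Plots share their year's conditions, so an
exchangeable within-year correlation is added: per-year covariance
τ²J + σ²·diag(1/n_ij), with (τ², σ²) method-of-moments estimates from the
WLS residuals (within-year residual cross-products estimate τ², clipped at
0). Estimation is GLS after block whitening; coefficient covariance is
scaled by the whitened residual variance over n − p, which makes the τ² = 0
case reproduce WLS exactly (a single plot per year forces τ̂² = 0 and does
the same). The reported ρ is τ̂²/(τ̂² + σ̂²/median n).

## The synthetic-data generator

The generator exists so that every stage is testable by parameter recovery.
It emulates the *structure* of a 24-year monitoring programme:

- **Temperatures:** T̄ₜ = 9 + 10·sin(2π(DOY − 109)/365.25) + AR(1) noise
  (marginal sd 3.5 °C, autocorrelation 0.7), i.e. a temperate-continental
  climatology with July maxima, January means near −1 °C, and realistic
  winter thaw days. The thaws matter: without them the deep-winter lags of
  the distributed-lag design would have no above-threshold days and the most
  distant spline coefficients would be unidentifiable. The record starts two
  calendar years before the first season so every candidate window is
  covered.
- **Seasons:** starts ~ N(day-of-year 143, sd 7), rounded to days; 6 plots
  per year by default (3–6 configurable); 50–300 tillers per plot-date;
  weekly sampling over 6–10 weeks.
- **Response:** TSM from the linear model with Var(ε) = σ²/n_ij. Defaults
  μ = 140, β₁ = −15, δ = −20, γ = 0, σ = 225 (per-observation sd ≈ 6 days
  at the average effort n ≈ 1400 tiller-dates) put mean TSM near 47 days
  with sd ≈ 16 — a 6–10-week growth period at the scale of the published
  estimates. μ is set so the linear predictor stays positive; a
  configuration whose *expected* TSM is negative raises an error, and the
  rare negative realization (<0.1% of records) is clipped at 0.
- **Trajectories:** density rises geometrically (×2 per week) from the start
  to the peak at start + TSM, then declines faster (×1/4 per week) — the
  left-skewed triangular shape of aphid seasons. Counts are Poisson around
  density × tillers; `count_noise="none"` emits exact densities.
- **Lag-varying truth:** any β₁ₗ vector; the bimodal preset places Gaussian
  negative windows (depth −35) at lags ~50–80 and ~90–110, the scale at
  which roughly 50 active lags average to the homogeneous β₁ ≈ −15.

Two access points with different purposes: `simulate_records` emits the
exact Gaussian regression rows the estimator assumes (used for CI-coverage
and recovery experiments — the frequentist statements are about the stated
model), while `simulate_panel` additionally rounds TSM to the weekly grid
and emits counts (used for round-trip and end-to-end pipeline tests). Grid
rounding adds ≈U(−3.5, 3.5) days of noise outside the fitted variance
model, so calibration is *not* asserted through the panel path.

**What the generator does not emulate,** hence what passing tests do not
show about field data: no mechanistic aphid dynamics (generations, natural
enemies, senescence timing), no temperature-triggered season start by
default (a DD-threshold start rule would confound start date with the
covariates; the default draws starts independently so the generator matches
the fitted model), no observation gaps or missing weeks, no spatial
structure among plots, and Gaussian — not count-process — TSM errors.

## Problem sizes and numerical conventions

Monte Carlo experiments in the test suite and acceptance script use 24 years
× 6 plots (144 records): 500 replicates for CI coverage and type-I error,
100 for power and lag-curve shape, 50 for L recovery (grid 20…120 step 5,
true L = 60 with μ = 190 and σ = 60 — the shorter all-warm window raises
DD5/L, and the strong-signal setting is what makes a 50-replicate recovery
experiment informative). Oracle checks (degree-day loop, Cox–de Boor
recursion, weighted normal equations) run on 100 random instances each;
exactness claims for sums are made on integer-valued temperatures, where
float64 summation is exact regardless of order. IRWLS tolerance 1e-10;
degenerate inputs (empty series, all-zero seasons, zero tillers, duplicate
observations, out-of-range temperatures beyond the −50…+110 °C instrument
range) raise errors naming the offending record.

## Known limitations

- Selecting L by profiled AIC and then reporting conditional-on-L inference
  understates uncertainty; assessing the variability induced by estimating
  L would need far more data (or a bootstrap, not implemented).
- The method-of-moments variance components in the random-year fit are
  simple and can be noisy in short panels; REML via a mixed-model package is
  a reasonable alternative when the sensitivity fit is of primary interest.
- The spline degree/knot defaults are conventions; conclusions about *where*
  the lag curve dips should be checked against K and degree perturbations.
- Absolute AIC values are not comparable across software conventions; only
  ΔAIC orderings are reproduced.
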