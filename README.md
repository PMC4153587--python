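# aphidlag

Distributed-lag regression of cereal-aphid season length on pre-season
degree-day temperature history.

## The problem

Aphid populations on winter wheat (*Metopolophium dirhodum*, *Sitobion
avenae*, *Rhopalosiphum padi*) grow from spring immigration to a mid-summer
peak, then collapse with crop senescence. The length of that growth period —
**TSM**, the days from the first non-zero density on a plot to its density
maximum — largely sets the peak abundance, and is itself regulated by the
temperatures of the months *before* the season starts: wheat develops above
0 °C, aphids only above 5 °C, so winters spent between 0 and 5 °C advance
the crop relative to the insect.

`aphidlag` is for ecologists and biostatisticians who want to fit this kind
of pre-season thermal-history model to count panels (year × plot × weekly
counts on 50–300 tillers) and a daily temperature record. It provides:

- degree-day covariates **DD5** (Σ T̄ₜ·I[T̄ₜ > 5]) and **DD05**
  (Σ T̄ₜ·I[0 ≤ T̄ₜ ≤ 5]) over the `L` days before each local season start;
- four heteroscedastic regression models, Var(ε_ij) = σ²/n_ij with n_ij the
  tillers inspected:

  `TSM_ij = μ + β₁·DD5_ij/L + δ·DD05_ij/L + γ·(previous-year term) + ε_ij`

  with the previous-year maximum density (model 1) or previous-year TSM
  (model 2) as the density-dependence correction, and their distributed-lag
  versions (models 3, 4) in which β₁ becomes lag-varying,
  β₁ₗ = Σ_k θ_k b_k(l), constrained to a B-spline basis of K+1 = 10
  functions (an Almon-type lag);
- profiled-AIC selection of the lag depth `L` over integer candidates;
- the fitted lag curve β̂₁ₗ with pointwise 95% bands, a joint Wald test of
  the DD5 effect, AIC model comparison, and a random-year-effect
  (exchangeable within-year correlation) sensitivity fit;
- a synthetic-data generator reproducing the study structure (24 years ×
  3–6 plots, weekly triangular density trajectories, season starts near
  day-of-year 143) so every stage is verifiable by parameter recovery.

See `docs/methods.md` for the statistical conventions and generator details.

## Worked example

Fit model 1 at L = 123 to a simulated study generated with
(β₁, δ, γ) = (−15, −20, 0):

```python
import aphidlag as al

config = al.SyntheticConfig(plots_min=6, plots_max=6)
temps, records = al.simulate_records(config, seed=1)

fit1 = al.fit_model(records, temps, al.DesignSpec(model_id=1, depth_L=123))
print(al.fit_table(fit1).round(4).to_string(index=False))
```

```
   Coefficient  Estimate  Standard error  p-value
         beta1  -15.0142          0.6159   0.0000
         delta  -19.4601          2.8716   0.0000
gamma_prev_max   -0.0485          0.0333   0.1473
```

Both degree-day effects are negative — warm pre-season days, and days in
the [0, 5] °C window, shorten the aphid growth period — while the
previous-year density term is indistinguishable from zero, exactly the
generating configuration. Profiling the lag depth on the same data,

```python
spec = al.DesignSpec(model_id=1, depth_L=123)
coarse = al.profile_L(records, temps, spec, range(40, 161, 5))
fine = al.profile_L(records, temps, spec,
                    range(coarse.best_L - 4, coarse.best_L + 5))
print(coarse.best_L, fine.best_L)   # -> 130 129  (generator truth: 123)
```

recovers a history depth within a week of the generating L = 123 — a
mid-May season start minus ~123 days points at the second half of January,
the tail of wheat vernalization. The distributed-lag model then shows
*which* past days matter (`examples/05_lag_curve.py`): under a generator
with two negative lag windows the fitted curve dips at lags 67 and 103, the
joint Wald test gives F(10, 131) ≈ 38 (p ≈ 1e-33), and model 3 beats
model 1 by ~100 AIC points.

The `examples/` directory has one short script per capability; a thin CLI
(`aphidlag simulate|ddays|tsm|fit|profile|lagcurve|compare`) covers the same
pipeline for file-based workflows.

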