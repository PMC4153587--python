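"""Distributed-lag model: which past days matter most?

Model 3 lets the DD5 coefficient vary by lag, constrained to a B-spline
basis of K+1 = 10 functions (an Almon-type distributed lag).  The data here
are generated with two negative lag windows (50-80 and 90-110 days before
the season start), and the fitted curve should find them.
"""

import numpy as np

import aphidlag as al

config = al.SyntheticConfig(
    plots_min=6, plots_max=6, lag_curve=al.bimodal_lag_curve(123)
)
temps, records = al.simulate_records(config, seed=1)

fit3 = al.fit_model(records, temps, al.DesignSpec(model_id=3, depth_L=123))
test = al.joint_dd5_test(fit3)
curve = al.lag_curve(fit3)

print(f"joint Wald test of beta_1l = 0 at every lag: "
      f"F({test.df1}, {test.df2}) = {test.statistic:.1f}, p = {test.pvalue:.2g}")
minima = np.sort(curve.local_minima()[:2])
print(f"two deepest local minima of the fitted curve: lags {list(minima)} "
      f"(true windows: 50-80 and 90-110)")
print()
print("curve every 10 lags (estimate with pointwise 95% band):")
sub = curve.as_frame().iloc[9::10]
print(sub.round(2).to_string(index=False))
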