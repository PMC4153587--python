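"""Degree-day covariates over a pre-season lag window.

DD5 sums daily means above 5 °C (the aphid developmental threshold) and DD05
those within [0, 5] °C (wheat develops, aphids do not), over the L days
before the local season start.  The per-lag contributions are what the
distributed-lag model weights day by day.
"""

import aphidlag as al

temps = al.simulate_temperature(al.SyntheticConfig(n_years=1), seed=4)
window = al.LagWindow(anchor_day="1987-05-23", depth_L=123)  # start DOY 143

d5 = al.dd5(temps, window)
d05 = al.dd05(temps, window)
x = al.lag_contributions(temps, window)

print(f"window: 123 days before {window.anchor_day.date()}")
print(f"DD5  = {d5:7.1f} degree-days  (DD5/L  = {d5 / 123:5.2f})")
print(f"DD05 = {d05:7.1f} degree-days  (DD05/L = {d05 / 123:5.2f})")
print(f"per-lag contributions sum to DD5: {abs(x.sum() - d5):.1e}")
print()
print("Recent lags (spring) carry most of DD5; distant lags (winter) little:")
for lo, hi in [(1, 30), (31, 60), (61, 90), (91, 123)]:
    share = x[lo - 1:hi].sum() / d5 * 100
    print(f"  lags {lo:3d}-{hi:3d}: {share:5.1f}% of DD5")
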