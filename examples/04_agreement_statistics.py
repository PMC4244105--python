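"""Bland-Altman agreement between two volumetry methods, with the
regression-based limits used when the bias grows with breast size.
"""

import numpy as np

from breastdens import bland_altman, linear_regression, regression_loa

rng = np.random.default_rng(0)
n = 37
manual_L = rng.uniform(0.3, 2.0, n)  # manual breast volumes in liters
# automatic method overestimates slightly, more so for larger breasts
auto_L = manual_L * 1.04 + 0.01 + rng.normal(0, 0.03, n)

ba = regression_loa(bland_altman(auto_L, manual_L))
print(f"mean bias (auto - manual): {ba.mean_bias * 1000:.1f} mL "
      f"+/- {ba.sd_diff * 1000:.1f} mL (SD)")
print(f"classic limits of agreement: [{ba.loa_low * 1000:.1f}, {ba.loa_high * 1000:.1f}] mL")

d = ba.regression_line
print(f"difference ~ average: d = {d.intercept * 1000:.1f} mL + {d.slope:.3f} * a "
      f"(slope p = {d.p_values[1]:.2g})")
for a in (0.5, 1.0, 2.0):
    lo, hi = ba.regression_loa[0](a), ba.regression_loa[1](a)
    print(f"  regression-based limits at a = {a:.1f} L: [{lo * 1000:.1f}, {hi * 1000:.1f}] mL")

fit = linear_regression(manual_L, auto_L)
print(f"auto ~ manual: slope {fit.slope:.3f} (95% CI {fit.conf_int[1][0]:.3f}"
      f"-{fit.conf_int[1][1]:.3f}), r = {fit.r:.3f}")
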