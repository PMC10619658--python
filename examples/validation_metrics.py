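"""Comparing simulated and measured probe speeds: NMAE and linear fit.

Hot-wire measurements are user-supplied in practice; here a synthetic
"measured" series is built from a simulated one with 8% noise so the
metrics have something to chew on.
"""
import numpy as np

from canopyflow import linear_fit, nmae

rng = np.random.default_rng(0)
simulated = np.concatenate([rng.uniform(1.0, 5.0, 15) for _ in range(3)])
measured = simulated * (1 + 0.08 * rng.standard_normal(simulated.size)) + 0.05

print(f"NMAE (mean-normalized): {nmae(simulated, measured):.2f}%")
fit = linear_fit(simulated, measured)
print(f"fit: M = {fit.slope:.4f} S + {fit.intercept:.4f}, "
      f"R^2 = {fit.r_squared:.4f}, n = {fit.n}")
# NMAE is mean |S - M| over mean M, in percent; the regression is of the
# measured values on the simulated ones, as in field validation studies.
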