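"""RMSE vs MRSE semantics and bootstrap confidence intervals.

RMSE scores every spot prediction individually; MRSE first averages the
predictions of each cavity, so symmetric per-spot errors cancel.  The two
metrics therefore reward different behaviour: per-spot precision vs
aggregate accuracy.
"""

import numpy as np

from pgtrange import bootstrap_ci, mrse, rmse

rng = np.random.default_rng(0)

# symmetric scatter: poor per-spot precision, perfect aggregate accuracy
y = np.repeat([0.0, 5.0, 10.0, 20.0], 20)
symmetric = y + rng.normal(0, 3.0, y.size)
print("symmetric 3 mm scatter:")
print(f"  RMSE = {rmse(y, symmetric):.2f} mm   MRSE = {mrse(y, symmetric):.2f} mm")

# constant bias: decent RMSE, but the aggregate is off for every cavity
biased = y + 2.0
print("constant +2 mm bias:")
print(f"  RMSE = {rmse(y, biased):.2f} mm   MRSE = {mrse(y, biased):.2f} mm")

lo, hi = bootstrap_ci(y, symmetric, "rmse", B=1000, level=0.95, seed=1)
print(f"bootstrap 95% CI of the RMSE: ({lo:.2f}, {hi:.2f}) mm over {y.size} spots")
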